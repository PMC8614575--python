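"""Seeded generators for every input the pipeline consumes.

Three forward models mirror the downstream estimators:

* a herd generator that inverts the emitter-ranking regression (observed
  CH4 = linear predictor + per-animal offset + noise),
* an in vitro generator producing cumulative gas curves, headspace CH4
  series and end-point VFA profiles from true two-pool Gompertz kinetics,
* a Dirichlet-multinomial OTU-table generator with a rumen-like default
  composition.

All generators are deterministic given (truth, seed), and with all noise
parameters at zero their outputs are exactly invertible by the matching
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gaskin, vfa as vfa_mod
from .errors import InvalidParameterError

# ---------------------------------------------------------------------------
# herd generation


@dataclass(frozen=True)
class HerdTruth:
    """True parameters of the herd-level CH4 model.

    Defaults are sized so that ranking the generated herd into 7 low / 7
    high cows yields observed group means near 331 and 442 g CH4/d.
    """

    n_cows: int = 14
    n_periods: int = 2
    dmi_mean: float = 20.6
    dmi_sd: float = 1.5
    bw_mean: float = 620.0
    bw_sd: float = 60.0
    intercept: float = 36.1
    beta_dmi: float = 14.0
    beta_bw: float = 0.1
    period_effects: tuple = (-5.0, 5.0)
    animal_offset_sd: float = 74.0
    residual_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cows < 2:
            raise InvalidParameterError("n_cows must be >= 2")
        if self.n_periods < 1:
            raise InvalidParameterError("n_periods must be >= 1")
        if len(self.period_effects) != self.n_periods:
            raise InvalidParameterError("period_effects must have n_periods entries")
        for name in ("dmi_sd", "bw_sd", "animal_offset_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")


@dataclass
class HerdSim:
    cows: pd.DataFrame  # cow_id, period, dmi, bw, ch4_obs
    offsets: pd.Series  # cow_id -> true animal offset (g/d)
    truth: HerdTruth


def gen_herd(truth: HerdTruth) -> HerdSim:
    """One record per cow x period, CH4 generated from the linear model."""
    rng = np.random.default_rng(truth.seed)
    cow_ids = [f"cow{i + 1:03d}" for i in range(truth.n_cows)]
    offsets = rng.normal(0.0, truth.animal_offset_sd, truth.n_cows)
    rows = []
    for ci, cow in enumerate(cow_ids):
        for pi in range(truth.n_periods):
            dmi = max(rng.normal(truth.dmi_mean, truth.dmi_sd), 1.0)
            bw = max(rng.normal(truth.bw_mean, truth.bw_sd), 100.0)
            mean = (truth.intercept + truth.beta_dmi * dmi + truth.beta_bw * bw
                    + truth.period_effects[pi] + offsets[ci])
            ch4 = max(mean + rng.normal(0.0, truth.residual_sd), 0.0)
            rows.append({"cow_id": cow, "period": f"P{pi + 1}", "dmi": dmi,
                         "bw": bw, "ch4_obs": ch4})
    cows = pd.DataFrame(rows)
    return HerdSim(cows=cows, offsets=pd.Series(offsets, index=cow_ids, name="offset"),
                   truth=truth)


# ---------------------------------------------------------------------------
# in vitro generation


@dataclass(frozen=True)
class PoolTruth:
    """True two-pool Gompertz parameters (per g DM)."""

    a1: float
    b1: float
    k1: float
    a2: float
    b2: float
    k2: float

    def __post_init__(self):
        if self.a1 < 0 or self.a2 < 0:
            raise InvalidParameterError("pool sizes must be nonnegative")
        if min(self.b1, self.b2, self.k1, self.k2) <= 0:
            raise InvalidParameterError("shapes and rates must be positive")

    def evaluate(self, t) -> np.ndarray:
        return gaskin.two_pool_gompertz(t, self.a1, self.b1, self.k1,
                                        self.a2, self.b2, self.k2)

    @property
    def asymptote(self) -> float:
        return self.a1 + self.a2


def pool_truth(asymptote: float, rate: float, b: float = 2.0,
               split: float = 0.6) -> PoolTruth:
    """Two-pool truth with a given total asymptote and composite rate.

    Pool 1 holds ``split`` of the asymptote; rates are chosen as
    k1 = (1 - (1 - split)/2) / split * rate and k2 = rate / 2 so that the
    pool-size-weighted composite rate equals ``rate``.
    """
    k2 = rate / 2.0
    k1 = (rate - (1.0 - split) * k2) / split
    return PoolTruth(a1=asymptote * split, b1=b, k1=k1,
                     a2=asymptote * (1.0 - split), b2=b, k2=k2)


@dataclass(frozen=True)
class TreatmentDesign:
    """Factor levels and replication of one or more incubation runs."""

    runs: tuple = (1,)
    emitters: tuple = ("low", "high")
    diets: tuple = ("S", "SB")
    cnsl_levels: tuple = ("without", "with")

    def cells(self):
        for run in self.runs:
            for emitter in self.emitters:
                for diet in self.diets:
                    for cnsl in self.cnsl_levels:
                        yield run, emitter, diet, cnsl


@dataclass(frozen=True)
class InVitroTruth:
    """True kinetics, concentration behavior and VFA profiles per treatment.

    ``gas_kinetics`` and ``ch4_kinetics`` map (diet, cnsl) to
    :class:`PoolTruth` (mL/g DM); ``vfa_proportions`` maps
    (emitter, diet, cnsl) to a seven-acid mmol/mol array summing to 1000;
    ``vfa_totals`` maps emitter to the true total VFA concentration.
    """

    gas_kinetics: dict
    ch4_kinetics: dict
    vfa_proportions: dict
    vfa_totals: dict
    blank_asymptote: float = 10.0
    blank_rate: float = 0.05
    blank_shape: float = 2.0
    blank_vfa_total: float = 6.0
    gas_noise_sd: float = 0.05
    conc_noise_sd: float = 0.002
    vfa_noise_sd: float = 0.0
    vfa_total_noise_sd: float = 0.0
    n_replicates: int = 3
    n_blanks: int = 3
    headspace_volume: float = gaskin.DEFAULT_HEADSPACE_ML
    sample_mass: float = 1.0
    horizon: float = 48.0
    step: float = 0.2
    sample_times: tuple = gaskin.PROTOCOL_SAMPLE_TIMES
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1 or self.n_blanks < 1:
            raise InvalidParameterError("replicate and blank counts must be >= 1")
        if self.headspace_volume <= 0:
            raise InvalidParameterError("headspace volume must be positive")
        if self.sample_mass <= 0:
            raise InvalidParameterError("sample mass must be positive")
        for props in self.vfa_proportions.values():
            arr = np.asarray(props, dtype=float)
            if arr.size != 7 or np.any(arr < 0):
                raise InvalidParameterError("VFA proportions must be 7 nonnegative values")
            if abs(arr.sum() - 1000.0) > 1e-9:
                raise InvalidParameterError("true VFA proportions must sum to 1000")


# Marginal effect sizes (per g DM) used to reconstruct full-factorial true
# kinetics; diet margins (S, SB) and additive levels (without, with CNSL).
_GAS_ASYMPTOTE = {"grand": 243.75, "diet": {"S": -23.25, "SB": 23.25},
                  "cnsl": {"without": 28.75, "with": -28.75}}
_GAS_RATE = {"grand": 0.05975, "diet": {"S": -0.01375, "SB": 0.01375},
             "cnsl": {"without": 0.00275, "with": -0.00275}}
_CH4_ASYMPTOTE = {"grand": 25.65, "diet": {"S": -3.325, "SB": 3.325},
                  "cnsl": {"without": 10.65, "with": -10.65}}
_CH4_RATE = {"grand": 0.0525, "diet": {"S": -0.00425, "SB": 0.00425},
             "cnsl": {"without": -0.00325, "with": 0.00325}}

# Seven-acid profile reconstruction: per-emitter grand means and additive
# deviations for the three major acids; minor acids held at their grand mean.
_VFA_CELLS = {
    "low": {
        "acetate": (565.0, {"S": 24.0, "SB": -24.0}, {"without": 25.5, "with": -25.5}),
        "propionate": (279.5, {"S": -13.5, "SB": 13.5}, {"without": -34.5, "with": 34.5}),
        "butyrate": (97.3, {"S": -11.7, "SB": 11.7}, {"without": 4.95, "with": -4.95}),
        "isobutyrate": (13.6, None, None),
        "valerate": (25.6, None, None),
        "isovalerate": (11.05, None, None),
        "caproate": (7.96, None, None),
    },
    "high": {
        "acetate": (550.5, {"S": 16.5, "SB": -16.5}, {"without": 47.5, "with": -47.5}),
        "propionate": (300.5, {"S": -14.5, "SB": 14.5}, {"without": -54.5, "with": 54.5}),
        "butyrate": (92.65, {"S": -6.05, "SB": 6.05}, {"without": 4.85, "with": -4.85}),
        "isobutyrate": (13.5, None, None),
        "valerate": (24.15, None, None),
        "isovalerate": (11.05, None, None),
        "caproate": (7.16, None, None),
    },
}


def _margin_value(spec: dict, diet: str, cnsl: str) -> float:
    return spec["grand"] + spec["diet"][diet] + spec["cnsl"][cnsl]


def default_invitro_truth(**overrides) -> InVitroTruth:
    """Truth calibrated to the study-scale treatment effects."""
    gas, ch4 = {}, {}
    for diet in ("S", "SB"):
        for cnsl in ("without", "with"):
            gas[(diet, cnsl)] = pool_truth(_margin_value(_GAS_ASYMPTOTE, diet, cnsl),
                                           _margin_value(_GAS_RATE, diet, cnsl))
            ch4[(diet, cnsl)] = pool_truth(_margin_value(_CH4_ASYMPTOTE, diet, cnsl),
                                           _margin_value(_CH4_RATE, diet, cnsl))
    props = {}
    for emitter, acids in _VFA_CELLS.items():
        for diet in ("S", "SB"):
            for cnsl in ("without", "with"):
                vals = []
                for acid in vfa_mod.ACIDS:
                    grand, ddev, cdev = acids[acid]
                    v = grand
                    if ddev is not None:
                        v += ddev[diet] + cdev[cnsl]
                    vals.append(v)
                arr = np.asarray(vals, dtype=float)
                props[(emitter, diet, cnsl)] = arr / arr.sum() * 1000.0
    defaults = dict(gas_kinetics=gas, ch4_kinetics=ch4, vfa_proportions=props,
                    vfa_totals={"low": 65.0, "high": 62.0})
    defaults.update(overrides)
    return InVitroTruth(**defaults)


@dataclass
class InVitroRun:
    gas_curves: list  # GasCurve, samples and blanks
    headspace_series: list  # HeadspaceSeries, samples only
    vfa_profiles: list  # VFAProfile, samples and blanks
    truth: InVitroTruth
    design: TreatmentDesign


def _blank_curve(truth: InVitroTruth, t: np.ndarray) -> np.ndarray:
    return truth.blank_asymptote * np.exp(
        -truth.blank_shape * np.exp(-truth.blank_rate * t))


def _noisy_cumulative(true_curve: np.ndarray, sd: float, rng) -> np.ndarray:
    """Additive Gaussian noise on increments, truncated at 0, re-accumulated."""
    inc = np.diff(true_curve, prepend=0.0)
    if sd > 0:
        inc = np.maximum(inc + rng.normal(0.0, sd, inc.shape), 0.0)
    return np.cumsum(inc)


def derive_conc_model(gas_truth: PoolTruth, ch4_truth: PoolTruth,
                      truth: InVitroTruth) -> gaskin.LogConcModel:
    """Log-time concentration model consistent with the true gas and CH4
    kinetics.

    The exact headspace fraction on the grid is recovered by inverting the
    per-interval CH4 bookkeeping (first interval carries no headspace term),
    then projected onto a + b*ln(t) by least squares over the full grid.
    """
    t = gaskin.time_grid(truth.horizon, truth.step)
    g = truth.sample_mass * gas_truth.evaluate(t)
    m = truth.sample_mass * ch4_truth.evaluate(t)
    dg = np.diff(g, prepend=0.0)
    dm = np.diff(m, prepend=0.0)
    v = truth.headspace_volume
    c = np.empty_like(t)
    c[0] = dm[0] / dg[0] if dg[0] > 0 else 0.0
    for i in range(1, t.size):
        c[i] = (dm[i] + v * c[i - 1]) / (dg[i] + v)
    design = np.column_stack([np.ones_like(t), np.log(t)])
    coef, *_ = np.linalg.lstsq(design, c, rcond=None)
    return gaskin.LogConcModel(a=float(coef[0]), b=float(coef[1]))


def _logistic_normal(props: np.ndarray, sd: float, rng) -> np.ndarray:
    """Perturb a 1000-sum composition on the log scale; exact when sd = 0."""
    if sd <= 0:
        return props.copy()
    z = np.log(np.maximum(props, 1e-12)) + rng.normal(0.0, sd, props.shape)
    ez = np.exp(z - z.max())
    return ez / ez.sum() * 1000.0


def gen_invitro_run(truth: InVitroTruth, design: TreatmentDesign) -> InVitroRun:
    """Gas curves, headspace series and VFA profiles for a treatment design."""
    rng = np.random.default_rng(truth.seed)
    t = gaskin.time_grid(truth.horizon, truth.step)
    blank_true = _blank_curve(truth, t)

    conc_models = {}
    for key in truth.ch4_kinetics:
        conc_models[key] = derive_conc_model(truth.gas_kinetics[key],
                                             truth.ch4_kinetics[key], truth)

    gas_curves, headspace_series, vfa_profiles = [], [], []
    for run in design.runs:
        for emitter in design.emitters:
            for b in range(truth.n_blanks):
                bid = f"r{run}_{emitter}_blank{b + 1}"
                vol = _noisy_cumulative(blank_true, truth.gas_noise_sd, rng)
                gas_curves.append(gaskin.GasCurve(
                    bid, t.copy(), vol, sample_mass=truth.sample_mass,
                    meta={"run": run, "emitter": emitter, "diet": None,
                          "cnsl": None, "replicate": b + 1, "is_blank": True}))
            for diet in design.diets:
                for cnsl in design.cnsl_levels:
                    key = (diet, cnsl)
                    gas_true = (blank_true
                                + truth.sample_mass * truth.gas_kinetics[key].evaluate(t))
                    conc = conc_models[key]
                    c_true = conc.evaluate(np.asarray(truth.sample_times))
                    for rep in range(truth.n_replicates):
                        bid = f"r{run}_{emitter}_{diet}_{cnsl}_rep{rep + 1}"
                        meta = {"run": run, "emitter": emitter, "diet": diet,
                                "cnsl": cnsl, "replicate": rep + 1, "is_blank": False}
                        vol = _noisy_cumulative(gas_true, truth.gas_noise_sd, rng)
                        gas_curves.append(gaskin.GasCurve(
                            bid, t.copy(), vol, sample_mass=truth.sample_mass,
                            meta=meta))
                        frac = c_true.copy()
                        if truth.conc_noise_sd > 0:
                            frac = frac + rng.normal(0.0, truth.conc_noise_sd, frac.shape)
                        frac = np.clip(frac, 0.0, 1.0)
                        headspace_series.append(gaskin.HeadspaceSeries(
                            bid, np.asarray(truth.sample_times, dtype=float), frac))
                    props = _logistic_normal(
                        np.asarray(truth.vfa_proportions[(emitter, diet, cnsl)]),
                        truth.vfa_noise_sd, rng)
                    total = truth.vfa_totals[emitter]
                    if truth.vfa_total_noise_sd > 0:
                        total = max(total + rng.normal(0.0, truth.vfa_total_noise_sd), 0.0)
                    vfa_profiles.append(vfa_mod.VFAProfile(
                        *props, total=total, mode="proportion",
                        meta={"run": run, "emitter": emitter, "diet": diet,
                              "cnsl": cnsl, "is_blank": False}))
            # blank VFA: baseline proportions at the blank total
            base = np.mean([truth.vfa_proportions[(emitter, d, c)]
                            for d in design.diets for c in design.cnsl_levels], axis=0)
            base = base / base.sum() * 1000.0
            total = truth.blank_vfa_total
            if truth.vfa_total_noise_sd > 0:
                total = max(total + rng.normal(0.0, truth.vfa_total_noise_sd), 0.0)
            vfa_profiles.append(vfa_mod.VFAProfile(
                *base, total=total, mode="proportion",
                meta={"run": run, "emitter": emitter, "diet": None,
                      "cnsl": None, "is_blank": True}))
    return InVitroRun(gas_curves=gas_curves, headspace_series=headspace_series,
                      vfa_profiles=vfa_profiles, truth=truth, design=design)


# ---------------------------------------------------------------------------
# OTU table generation


@dataclass(frozen=True)
class CommunityTruth:
    """Dirichlet-multinomial community model.

    ``composition`` sums to 1; ``group_effect`` holds per-taxon multiplicative
    fold changes applied to the "high" group (the shifted composition is
    renormalized). ``overdispersion`` is the Dirichlet concentration
    (``numpy.inf`` gives the plain multinomial limit).
    """

    taxa: tuple  # OTU ids
    taxonomies: tuple  # lineage strings, parallel to taxa
    composition: tuple  # proportions, parallel to taxa
    overdispersion: float = 110.0
    library_mean: float = 20000.0
    library_sd: float = 2000.0
    group_effect: tuple = None
    n_per_group: int = 7
    seed: int = 0

    def __post_init__(self):
        comp = np.asarray(self.composition, dtype=float)
        if len(self.taxa) != len(self.taxonomies) or len(self.taxa) != comp.size:
            raise InvalidParameterError("taxa, taxonomies and composition must align")
        if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("composition must sum to 1 +/- 1e-9")
        if self.overdispersion <= 0:
            raise InvalidParameterError("overdispersion must be positive")
        if self.group_effect is not None:
            ge = np.asarray(self.group_effect, dtype=float)
            if ge.size != comp.size or np.any(ge <= 0):
                raise InvalidParameterError("group_effect must be positive, one per taxon")
        if self.n_per_group < 1:
            raise InvalidParameterError("n_per_group must be >= 1")


def _default_taxa():
    """Rumen-like default community: taxon id, lineage, proportion of total."""
    bac = "d__Bacteria"
    arc = "d__Archaea;p__Euryarchaeota"
    mbb = (arc + ";c__Methanobacteria;o__Methanobacteriales;"
           "f__Methanobacteriaceae;g__Methanobrevibacter")
    bact = bac + ";p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales"
    firm = bac + ";p__Firmicutes;c__Clostridia;o__Clostridiales"
    entries = [
        # Bacteroidetes, 62.5% of the total; Prevotella 35.6%
        ("otu_prev1", bact + ";f__Prevotellaceae;g__Prevotella;s__", 0.120),
        ("otu_prev2", bact + ";f__Prevotellaceae;g__Prevotella;s__", 0.090),
        ("otu_prev3", bact + ";f__Prevotellaceae;g__Prevotella;s__", 0.070),
        ("otu_prev4", bact + ";f__Prevotellaceae;g__Prevotella;s__", 0.046),
        ("otu_prev5", bact + ";f__Prevotellaceae;g__Prevotella;s__", 0.030),
        ("otu_prevfam", bact + ";f__Prevotellaceae;g__;s__", 0.065),
        ("otu_riken", bact + ";f__Rikenellaceae;g__;s__", 0.049),
        ("otu_rf16", bact + ";f__RF16;g__;s__", 0.080),
        ("otu_bacter", bact + ";f__Bacteroidaceae;g__Bacteroides;s__", 0.075),
        # Firmicutes, 21.2%
        ("otu_rumino", firm + ";f__Ruminococcaceae;g__Ruminococcus;s__", 0.022),
        ("otu_ruminofam", firm + ";f__Ruminococcaceae;g__;s__", 0.030),
        ("otu_succini", firm + ";f__Acidaminococcaceae;g__Succiniclasticum;s__", 0.013),
        ("otu_butyri", firm + ";f__Lachnospiraceae;g__Butyrivibrio;s__", 0.050),
        ("otu_lachno", firm + ";f__Lachnospiraceae;g__;s__", 0.060),
        ("otu_clost", firm + ";f__Clostridiaceae;g__Clostridium;s__", 0.037),
        # Proteobacteria, 6.2%
        ("otu_succiniv", bac + ";p__Proteobacteria;c__Gammaproteobacteria;"
                         "o__Aeromonadales;f__Succinivibrionaceae;g__;s__", 0.052),
        ("otu_desulfo", bac + ";p__Proteobacteria;c__Deltaproteobacteria;"
                        "o__Desulfovibrionales;f__Desulfovibrionaceae;"
                        "g__Desulfovibrio;s__", 0.010),
        # minor bacterial phyla, 9.3%
        ("otu_fibro", bac + ";p__Fibrobacteres;c__Fibrobacteria;o__Fibrobacterales;"
                      "f__Fibrobacteraceae;g__Fibrobacter;s__", 0.030),
        ("otu_trepo", bac + ";p__Spirochaetes;c__Spirochaetia;o__Spirochaetales;"
                      "f__Spirochaetaceae;g__Treponema;s__", 0.025),
        ("otu_chloro", bac + ";p__Chloroflexi;c__Anaerolineae;o__Anaerolineales;"
                       "f__Anaerolineaceae;g__;s__", 0.010),
        ("otu_verruco", bac + ";p__Verrucomicrobia;c__Verrucomicrobiae;"
                        "o__Verrucomicrobiales;f__;g__;s__", 0.015),
        ("otu_actino", bac + ";p__Actinobacteria;c__Actinobacteria;"
                       "o__Bifidobacteriales;f__;g__;s__", 0.013),
    ]
    # Archaea, 0.8% of the total; clade split of the archaeal fraction:
    # SGMT 69.8%, RO 21.5%, other Methanobrevibacter 2.4%,
    # Methanosphaera 3.2%, Methanomassiliicoccales 2.4%, other 0.7%.
    arch_frac = 0.008
    arch = [
        ("otu_mbb_gott", mbb + ";s__Methanobrevibacter gottschalkii", 0.350),
        ("otu_mbb_smith", mbb + ";s__Methanobrevibacter smithii", 0.200),
        ("otu_mbb_mill", mbb + ";s__Methanobrevibacter millerae", 0.100),
        ("otu_mbb_thau", mbb + ";s__Methanobrevibacter thaueri", 0.048),
        ("otu_mbb_rumi", mbb + ";s__Methanobrevibacter ruminantium", 0.160),
        ("otu_mbb_olle", mbb + ";s__Methanobrevibacter olleyae", 0.055),
        ("otu_mbb_uncl", mbb + ";s__", 0.024),
        ("otu_msp", arc + ";c__Methanobacteria;o__Methanobacteriales;"
                    "f__Methanobacteriaceae;g__Methanosphaera;s__", 0.032),
        ("otu_mmc", arc + ";c__Thermoplasmata;o__Methanomassiliicoccales;"
                    "f__Methanomethylophilaceae;g__;s__", 0.024),
        ("otu_arch_other", arc + ";c__;o__;f__;g__;s__", 0.007),
    ]
    entries += [(name, tax, frac * arch_frac) for name, tax, frac in arch]
    names = tuple(e[0] for e in entries)
    taxes = tuple(e[1] for e in entries)
    comp = np.array([e[2] for e in entries], dtype=float)
    comp = comp / comp.sum()
    return names, taxes, tuple(comp)


def default_community_truth(**overrides) -> CommunityTruth:
    names, taxes, comp = _default_taxa()
    defaults = dict(taxa=names, taxonomies=taxes, composition=comp)
    defaults.update(overrides)
    return CommunityTruth(**defaults)


def gen_otu_table(truth: CommunityTruth):
    """Dirichlet-multinomial OTU table with low/high group labels.

    Samples are paired into runs 1..n_per_group (one low and one high per
    run). With ``group_effect`` absent or identically 1 the two groups are
    exchangeable.
    """
    from .community import OtuTable  # local import to avoid a cycle

    rng = np.random.default_rng(truth.seed)
    comp = np.asarray(truth.composition, dtype=float)
    comps = {"low": comp}
    if truth.group_effect is None:
        comps["high"] = comp
    else:
        shifted = comp * np.asarray(truth.group_effect, dtype=float)
        comps["high"] = shifted / shifted.sum()

    rows, meta_rows, index = [], [], []
    for group in ("low", "high"):
        for i in range(truth.n_per_group):
            sid = f"{group}_{i + 1}"
            lib = max(int(round(rng.normal(truth.library_mean, truth.library_sd))), 1)
            if np.isinf(truth.overdispersion):
                p = comps[group]
            else:
                p = rng.dirichlet(truth.overdispersion * comps[group])
            rows.append(rng.multinomial(lib, p))
            meta_rows.append({"emitter": group, "run": i + 1})
            index.append(sid)
    counts = pd.DataFrame(rows, index=index, columns=list(truth.taxa))
    metadata = pd.DataFrame(meta_rows, index=index)
    taxonomy = pd.Series(dict(zip(truth.taxa, truth.taxonomies)), name="taxonomy")
    return OtuTable(counts=counts, metadata=metadata, taxonomy=taxonomy)
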