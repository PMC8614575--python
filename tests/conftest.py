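"""Shared fixtures: expensive simulations are session-scoped so the unit
suite and the acceptance suite reuse them."""

import numpy as np
import pytest

from rumeth import community, synthio


@pytest.fixture(scope="session")
def null_permanova_pvalues():
    """400 permutational-MANOVA p-values from exchangeable-group tables.

    Generated once: group_effect is absent, so low/high labels are
    exchangeable and the p-values should be uniform on the achievable grid.
    """
    pvals = []
    for s in range(400):
        truth = synthio.default_community_truth(seed=20000 + s)
        table = synthio.gen_otu_table(truth)
        d = community.beta_distance(table, "bray_curtis")
        res = community.permanova(d, table.metadata["emitter"],
                                  n_permutations=199, seed=s)
        pvals.append(res.p_value)
    return np.array(pvals)


@pytest.fixture(scope="session")
def noisefree_invitro_run():
    """One noise-free incubation run for the low inoculum."""
    truth = synthio.default_invitro_truth(
        gas_noise_sd=0.0, conc_noise_sd=0.0, vfa_noise_sd=0.0, seed=7)
    design = synthio.TreatmentDesign(runs=(1,), emitters=("low",))
    return synthio.gen_invitro_run(truth, design)


@pytest.fixture(scope="session")
def default_herd_sim():
    return synthio.gen_herd(synthio.HerdTruth(seed=11))
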