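import numpy as np
import pandas as pd
import pytest

import sigflow as sf


@pytest.fixture
def six_shoot():
    """Six equidistant shoots on a branch, fruit on shoots 1, 2 and 4."""
    return sf.build_linear_branch(n_shoots=6, spacing=0.15, shoot_length=0.10,
                                  fruiting={1, 2, 4},
                                  leafy=set(range(1, 7)), leaf_area=100.0)


@pytest.fixture
def two_branch_fruit():
    """One fully fruiting branch, one defruited branch; leaves everywhere."""
    return sf.build_two_branch(shoots_per_branch=6, layout="by_branch",
                               organ="fruit")


@pytest.fixture
def four_branch():
    return sf.build_four_branch(shoots_per_branch=4)


def synthetic_inhibiting_observations(structures, r_true, t_true, v_true,
                                      noise_sd=0.0, seed=0):
    """Observed-FI table generated by the model itself at known parameters."""
    rng = np.random.default_rng(seed)
    rows = []
    for sid in sorted(structures):
        tree = structures[sid]
        D = sf.compute_distances(tree)
        qf = sf.accumulate(
            sf.allocate(sf.source_vector(tree, "inhibiting"), D, r_true)).QF
        P = sf.prob_inhibition(qf, sf.SigmoidParams(t_true, v_true,
                                                    "inhibiting"))
        labels = np.array([tree.shoots[tree.sams[m].shoot_id].part_label
                           for m in D.sam_ids])
        for lab in sorted(set(labels)):
            val = float(P[labels == lab].mean())
            if noise_sd:
                val = min(1.0, max(0.0, val + rng.normal(0.0, noise_sd)))
            rows.append(dict(structure_id=sid, part_label=lab,
                             fi_observed=val, n_replicates=3))
    return sf.ObservationSet(pd.DataFrame(rows))
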