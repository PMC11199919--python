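"""Builders shared across test modules."""

import numpy as np
import pandas as pd

from hsm.prep import assign_background_folds, make_folds, sample_background
from hsm.swd import SWDTable, build_swd
from hsm.synthetic import make_paired_stacks, sample_presences


def make_swd(n_presence=100, n_background=500, n_vars=3, seed=0, shift=1.0, k_folds=None):
    """SWD with presences shifted on the first variable; optional random folds."""
    rng = np.random.default_rng(seed)
    cols = {}
    for j in range(n_vars):
        mu = shift if j == 0 else 0.0
        cols[f"v{j}"] = np.concatenate(
            [rng.normal(mu, 1, n_presence), rng.normal(0, 1, n_background)]
        )
    n = n_presence + n_background
    df = pd.DataFrame(cols)
    df.insert(0, "species", ["sp"] * n_presence + ["background"] * n_background)
    df.insert(1, "x", rng.uniform(0, 1000, n))
    df.insert(2, "y", rng.uniform(0, 1000, n))
    df.insert(3, "is_presence", [1] * n_presence + [0] * n_background)
    fold = rng.integers(1, k_folds + 1, n) if k_folds else np.nan
    df.insert(4, "fold", fold)
    return SWDTable(df)


def make_study(seed=0, *, shape=(64, 64), n_fine=6, n_coarse=3, n_presences=200,
               clustering=5, k=5, n_background=1500):
    """Full small synthetic study: stacks, truth, fold-labeled SWD tables."""
    fine, coarse, truth = make_paired_stacks(n_fine, n_coarse, shape=shape, seed=seed)
    occ = sample_presences(truth, n_presences, clustering=clustering, seed=seed + 100)
    scheme = make_folds(occ, k, seed=seed + 200)
    occf = occ.with_fold(scheme.labels)
    bg = assign_background_folds(sample_background(fine, n_background, seed=seed + 300), scheme)
    return {
        "fine": fine,
        "coarse": coarse,
        "truth": truth,
        "swd_fine": build_swd(fine, occf, bg),
        "swd_coarse": build_swd(coarse, occf, bg),
        "scheme": scheme,
    }
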