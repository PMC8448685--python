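import numpy as np
import pandas as pd
import pytest

from delaynet.network import ConnectomeStack, DelayNetwork


def roi_table(n, hemispheres=None, subcortical=None):
    """Minimal ROI table for toy networks."""
    hemispheres = hemispheres or ["L"] * n
    subcortical = subcortical if subcortical is not None else [False] * n
    return pd.DataFrame({
        "name": [f"roi{i:02d}" for i in range(n)],
        "hemisphere": hemispheres,
        "is_subcortical": subcortical,
    })


def delay_net(tau, rois=None, allow_zero=False):
    """Wrap a symmetric delay matrix into a DelayNetwork.

    With ``allow_zero=True`` every off-diagonal pair is coupled and zero
    delays are permitted (instantaneous-coupling toy networks).
    """
    tau = np.asarray(tau, dtype=float)
    if allow_zero:
        coupling = np.ones_like(tau, dtype=bool)
        np.fill_diagonal(coupling, False)
    else:
        coupling = tau > 0
    return DelayNetwork(tau=tau, coupling=coupling,
                        rois=rois if rois is not None else roi_table(len(tau)),
                        allow_zero_delay=allow_zero)


def random_delay_net(rng, n_min=4, n_max=8, density=0.6,
                     w_lo=0.5, w_hi=3.0):
    """Random positive-weight undirected graph as a DelayNetwork."""
    n = int(rng.integers(n_min, n_max + 1))
    tau = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    mask = rng.random(iu.size) < density
    w = rng.uniform(w_lo, w_hi, iu.size)
    tau[iu[mask], ju[mask]] = w[mask]
    tau[ju[mask], iu[mask]] = w[mask]
    return DelayNetwork(tau=tau, coupling=tau > 0, rois=roi_table(n))


def edge_stack(counts, length=0.1, diameter=3.0, mtv=0.31896484,
               fr=0.5, fcsf=0.1, n_rois=3):
    """Stack with a single (0, 1) edge; ``counts`` gives one streamline
    count per subject (0 = edge absent for that subject)."""
    counts = np.asarray(counts, dtype=float)
    s = counts.size
    weights = {w: np.zeros((s, n_rois, n_rois)) for w in
               ("count", "length", "diameter", "mtv", "fr", "fcsf")}
    vals = {"length": length, "diameter": diameter, "mtv": mtv,
            "fr": fr, "fcsf": fcsf}
    for i, c in enumerate(counts):
        if c > 0:
            weights["count"][i, 0, 1] = weights["count"][i, 1, 0] = c
            for w, v in vals.items():
                weights[w][i, 0, 1] = weights[w][i, 1, 0] = v
    return ConnectomeStack(
        rois=roi_table(n_rois),
        subjects=[f"sub-{i + 1:02d}" for i in range(s)],
        weights=weights,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
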