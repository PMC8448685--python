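"""Connectome containers and group-network assembly.

A :class:`ConnectomeStack` holds, for each subject, six symmetric ROI x ROI
matrices: streamline count, mean streamline length (m), mean axon diameter
(um), mean MTV, mean restricted fraction f_r and mean CSF fraction f_csf.
:func:`group_average` applies the group inclusion rule — an edge is retained
iff strictly more than ``min_count`` streamlines are present in at least
``min_subjects`` subjects — and averages the remaining weights over exactly
the subjects that pass the count criterion for that edge.  Conduction delays
are computed at the subject level (length / Rushton velocity) and averaged
over the same contributors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import micro
from .errors import (
    DomainError,
    EmptyNetworkError,
    ValidationError,
)

WEIGHT_NAMES = ("count", "length", "diameter", "mtv", "fr", "fcsf")

__all__ = [
    "WEIGHT_NAMES",
    "ConnectomeStack",
    "GroupNetwork",
    "DelayNetwork",
    "subject_delays",
    "subject_velocities",
    "group_average",
    "exclude_rois",
    "filter_small_diameter",
    "to_delay_network",
]


def _check_square_symmetric(name: str, mat: np.ndarray, n: int) -> None:
    if mat.shape != (n, n):
        raise ValidationError(f"{name}: expected shape ({n}, {n}), got {mat.shape}")
    if not np.allclose(mat, mat.T, rtol=0, atol=0):
        raise ValidationError(f"{name}: matrix is not symmetric")
    if np.any(np.diagonal(mat) != 0):
        raise ValidationError(f"{name}: diagonal must be zero")


def _validate_roi_table(rois: pd.DataFrame) -> pd.DataFrame:
    required = {"name", "hemisphere", "is_subcortical"}
    missing = required - set(rois.columns)
    if missing:
        raise ValidationError(f"ROI table missing columns: {sorted(missing)}")
    if rois["name"].duplicated().any():
        raise ValidationError("ROI table contains duplicate names")
    return rois.reset_index(drop=True)


@dataclass
class ConnectomeStack:
    """Per-subject connectivity matrices over a shared ROI parcellation.

    Attributes
    ----------
    rois : pandas.DataFrame
        Columns ``name``, ``hemisphere`` ('L'/'R'), ``is_subcortical`` (bool).
    subjects : list of str
        Ordered subject identifiers.
    weights : dict of str -> ndarray
        One ``(n_subjects, n_rois, n_rois)`` array per weight in
        :data:`WEIGHT_NAMES`; every slice symmetric with zero diagonal, and
        every weight zero wherever the subject's streamline count is zero.
    """

    rois: pd.DataFrame
    subjects: list[str]
    weights: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rois = _validate_roi_table(self.rois)
        self.validate()

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def validate(self) -> None:
        n, s = self.n_rois, self.n_subjects
        missing = set(WEIGHT_NAMES) - set(self.weights)
        if missing:
            raise ValidationError(f"stack missing weights: {sorted(missing)}")
        for name in WEIGHT_NAMES:
            arr = np.asarray(self.weights[name], dtype=float)
            if arr.shape != (s, n, n):
                raise ValidationError(
                    f"weight '{name}': expected shape ({s}, {n}, {n}), got {arr.shape}"
                )
            for i in range(s):
                _check_square_symmetric(f"{name}[{self.subjects[i]}]", arr[i], n)
            self.weights[name] = arr
        count = self.weights["count"]
        if np.any(count < 0) or np.any(count != np.round(count)):
            raise ValidationError("streamline counts must be non-negative integers")
        absent = count == 0
        for name in WEIGHT_NAMES[1:]:
            if np.any(self.weights[name][absent] != 0):
                raise ValidationError(
                    f"weight '{name}' non-zero on an edge with zero streamline count"
                )

    # ---- stack directory I/O -------------------------------------------
    def to_dir(self, path: str | Path) -> Path:
        """Write ``sub-XX_<weight>.csv`` matrices plus ``rois.csv``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        names = list(self.rois["name"])
        self.rois.to_csv(path / "rois.csv", index=False)
        for i, sub in enumerate(self.subjects):
            for w in WEIGHT_NAMES:
                df = pd.DataFrame(self.weights[w][i], index=names, columns=names)
                df.to_csv(path / f"{sub}_{w}.csv")
        if self.meta:
            (path / "truth.json").write_text(json.dumps(self.meta, default=_jsonify))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "ConnectomeStack":
        path = Path(path)
        rois = pd.read_csv(path / "rois.csv")
        subjects = sorted(
            {f.name.rsplit("_", 1)[0] for f in path.glob("*_count.csv")}
        )
        if not subjects:
            raise ValidationError(f"no subject matrices found in {path}")
        weights = {}
        for w in WEIGHT_NAMES:
            mats = []
            for sub in subjects:
                df = pd.read_csv(path / f"{sub}_{w}.csv", index_col=0)
                mats.append(df.to_numpy(dtype=float))
            weights[w] = np.stack(mats)
        meta = {}
        truth = path / "truth.json"
        if truth.exists():
            meta = json.loads(truth.read_text())
        return cls(rois=rois, subjects=subjects, weights=weights, meta=meta)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class GroupNetwork:
    """Group-averaged network after the inclusion rule.

    ``adjacency`` is boolean; every weight matrix is zero off the adjacency
    pattern; ``n_contrib`` records how many subjects contributed per edge.
    """

    rois: pd.DataFrame
    adjacency: np.ndarray
    length: np.ndarray
    diameter: np.ndarray
    gratio: np.ndarray
    velocity: np.ndarray
    delay: np.ndarray
    n_contrib: np.ndarray

    def __post_init__(self):
        self.rois = _validate_roi_table(self.rois)
        n = len(self.rois)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        _check_square_symmetric("adjacency", self.adjacency.astype(int), n)
        for name in ("length", "diameter", "gratio", "velocity", "delay"):
            mat = np.asarray(getattr(self, name), dtype=float)
            _check_square_symmetric(name, mat, n)
            if np.any(mat[~self.adjacency] != 0):
                raise ValidationError(f"{name} non-zero off the adjacency pattern")
            setattr(self, name, mat)
        if np.any(self.delay[self.adjacency] <= 0):
            raise ValidationError("delay must be > 0 on every retained edge")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_table(self) -> pd.DataFrame:
        """One row per undirected retained edge, with all mean weights."""
        i, j = np.where(np.triu(self.adjacency, k=1))
        names = self.rois["name"].to_numpy()
        return pd.DataFrame(
            {
                "roi_a": names[i],
                "roi_b": names[j],
                "length_m": self.length[i, j],
                "diameter_um": self.diameter[i, j],
                "gratio": self.gratio[i, j],
                "velocity_m_per_s": self.velocity[i, j],
                "delay_s": self.delay[i, j],
                "n_contrib": self.n_contrib[i, j],
            }
        )

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        names = list(self.rois["name"])
        self.rois.to_csv(path / "rois.csv", index=False)
        for w in ("length", "diameter", "gratio", "velocity", "delay"):
            pd.DataFrame(getattr(self, w), index=names, columns=names).to_csv(
                path / f"group_{w}.csv"
            )
        pd.DataFrame(self.n_contrib, index=names, columns=names).to_csv(
            path / "group_provenance.csv"
        )
        return path


@dataclass
class DelayNetwork:
    """Symmetric delay matrix tau (s) + binary coupling matrix.

    This is the object both the graph stage and the Kuramoto stage consume:
    ``coupling[n, p]`` flags the presence of a connection and ``tau[n, p]``
    its conduction delay (strictly positive where coupled, zero elsewhere).
    """

    tau: np.ndarray
    coupling: np.ndarray
    rois: pd.DataFrame
    #: permit tau == 0 on coupled edges (instantaneous coupling, e.g. the
    #: zero-delay limit in simulations); path analyses still require tau > 0
    allow_zero_delay: bool = False

    def __post_init__(self):
        self.rois = _validate_roi_table(self.rois)
        n = len(self.rois)
        self.tau = np.asarray(self.tau, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=bool)
        _check_square_symmetric("tau", self.tau, n)
        _check_square_symmetric("coupling", self.coupling.astype(int), n)
        lo = 0 if self.allow_zero_delay else None
        if lo is None and np.any(self.tau[self.coupling] <= 0):
            raise ValidationError("tau must be > 0 wherever coupling is 1")
        if lo == 0 and np.any(self.tau[self.coupling] < 0):
            raise ValidationError("tau must be >= 0 wherever coupling is 1")
        if np.any(self.tau[~self.coupling] != 0):
            raise ValidationError("tau must be 0 wherever coupling is 0")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        names = list(self.rois["name"])
        self.rois.to_csv(path / "rois.csv", index=False)
        pd.DataFrame(self.tau, index=names, columns=names).to_csv(path / "tau.csv")
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "DelayNetwork":
        path = Path(path)
        rois = pd.read_csv(path / "rois.csv")
        tau = pd.read_csv(path / "tau.csv", index_col=0).to_numpy(dtype=float)
        return cls(tau=tau, coupling=tau > 0, rois=rois)


# ---------------------------------------------------------------------------
# subject-level computation


def subject_velocities(stack: ConnectomeStack,
                       k_rushton: float = micro.DEFAULT_K_RUSHTON):
    """Per-subject g-ratio and Rushton velocity matrices.

    Returns ``(gratio, velocity, valid)`` arrays of shape (S, N, N).  An edge
    is *valid* for a subject when it has streamlines, a positive AVF (so the
    g-ratio is defined) and a strictly positive velocity (g < 1 and d > 0).
    Invalid-but-present edges are dropped with a warning.
    """
    present = stack.weights["count"] > 0
    mtv = stack.weights["mtv"]
    avf = micro.compute_avf(mtv, stack.weights["fcsf"], stack.weights["fr"],
                            where=present)
    defined = present & (avf > 0)
    g = micro.compute_gratio(mtv, avf, where=defined)
    v = micro.rushton_velocity(stack.weights["diameter"], g, k_rushton,
                               where=defined)
    valid = defined & (v > 0)
    n_dropped = int((present & ~valid).sum()) // 2
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} subject-level edges with undefined g-ratio "
            "or zero velocity (g = 1 or d = 0)",
            stacklevel=2,
        )
    g = np.where(valid, g, 0.0)
    v = np.where(valid, v, 0.0)
    return g, v, valid


def subject_delays(stack: ConnectomeStack,
                   k_rushton: float = micro.DEFAULT_K_RUSHTON) -> np.ndarray:
    """Per-subject conduction delay matrices (s), zero where undefined."""
    _, v, valid = subject_velocities(stack, k_rushton)
    return micro.conduction_delay(stack.weights["length"], v, where=valid)


def _masked_mean(values: np.ndarray, mask: np.ndarray, retained: np.ndarray):
    """Mean of ``values`` over the subject axis restricted to ``mask``."""
    n = mask.sum(axis=0)
    total = np.where(mask, values, 0.0).sum(axis=0)
    out = np.zeros(values.shape[1:])
    sel = retained & (n > 0)
    out[sel] = total[sel] / n[sel]
    return out


def group_average(stack: ConnectomeStack, min_count: int = 4,
                  min_subjects: int = 9, *,
                  k_rushton: float = micro.DEFAULT_K_RUSHTON,
                  delay_aggregation: str = "subject_mean") -> GroupNetwork:
    """Build the group network under the streamline-count inclusion rule.

    An edge is retained iff strictly more than ``min_count`` streamlines are
    present in at least ``min_subjects`` subjects (defaults: > 4 streamlines
    in >= 9 of 14 subjects, a balance between false positives and false
    negatives in group tractography).  Retained-edge weights are means over
    exactly the contributing subjects; subjects failing the count criterion
    contribute nothing (no zero-imputation).

    ``delay_aggregation`` selects how the group delay is formed:
    ``"subject_mean"`` (default) averages subject-level delays;
    ``"ratio_of_means"`` divides group mean length by group mean velocity.
    """
    if min_subjects > stack.n_subjects:
        raise ValidationError(
            f"min_subjects={min_subjects} exceeds number of subjects "
            f"({stack.n_subjects})"
        )
    if delay_aggregation not in ("subject_mean", "ratio_of_means"):
        raise ValidationError(
            f"unknown delay_aggregation '{delay_aggregation}'"
        )
    contrib = stack.weights["count"] > min_count
    n_contrib = contrib.sum(axis=0)
    adjacency = n_contrib >= min_subjects
    np.fill_diagonal(adjacency, False)
    if not adjacency.any():
        raise EmptyNetworkError(
            "no edge passes the inclusion rule "
            f"(count > {min_count} in >= {min_subjects} subjects)"
        )

    g_s, v_s, valid = subject_velocities(stack, k_rushton)
    delay_s = micro.conduction_delay(stack.weights["length"], v_s, where=valid)
    dcontrib = contrib & valid  # contributors with a defined delay

    length = _masked_mean(stack.weights["length"], contrib, adjacency)
    diameter = _masked_mean(stack.weights["diameter"], contrib, adjacency)
    gratio = _masked_mean(g_s, dcontrib, adjacency)
    velocity = _masked_mean(v_s, dcontrib, adjacency)
    if delay_aggregation == "subject_mean":
        delay = _masked_mean(delay_s, dcontrib, adjacency)
    else:
        delay = np.zeros_like(length)
        ok = adjacency & (velocity > 0)
        delay[ok] = length[ok] / velocity[ok]

    # retained edges whose every contributor lacked a defined velocity have
    # no delay; they cannot enter a delay-weighted network
    undefined = adjacency & (delay <= 0)
    if undefined.any():
        warnings.warn(
            f"dropping {int(undefined.sum()) // 2} retained edges with no "
            "defined group delay",
            stacklevel=2,
        )
        adjacency = adjacency & ~undefined
        if not adjacency.any():
            raise EmptyNetworkError("no retained edge has a defined delay")

    def _maskout(m):
        return np.where(adjacency, m, 0.0)

    return GroupNetwork(
        rois=stack.rois.copy(),
        adjacency=adjacency,
        length=_maskout(length),
        diameter=_maskout(diameter),
        gratio=_maskout(gratio),
        velocity=_maskout(velocity),
        delay=_maskout(delay),
        n_contrib=np.where(adjacency, n_contrib, 0),
    )


def exclude_rois(obj, labels):
    """Remove ROIs by name from a :class:`ConnectomeStack` or network.

    Duplicate labels are deduplicated; unknown labels raise a
    :class:`ValidationError` listing every unknown name.  Used to drop
    regions outside the analysis (e.g. cerebellum and brainstem).
    """
    labels = list(dict.fromkeys(labels))  # dedupe, preserve order
    names = list(obj.rois["name"])
    unknown = [l for l in labels if l not in names]
    if unknown:
        raise ValidationError(f"unknown ROI labels: {unknown}")
    keep = np.array([name not in labels for name in names])
    idx = np.where(keep)[0]
    rois = obj.rois.iloc[idx].reset_index(drop=True)

    if isinstance(obj, ConnectomeStack):
        weights = {
            w: obj.weights[w][:, idx][:, :, idx] for w in WEIGHT_NAMES
        }
        return ConnectomeStack(rois=rois, subjects=list(obj.subjects),
                               weights=weights, meta=dict(obj.meta))
    if isinstance(obj, GroupNetwork):
        def sub(m):
            return np.asarray(m)[np.ix_(idx, idx)]

        return GroupNetwork(
            rois=rois, adjacency=sub(obj.adjacency), length=sub(obj.length),
            diameter=sub(obj.diameter), gratio=sub(obj.gratio),
            velocity=sub(obj.velocity), delay=sub(obj.delay),
            n_contrib=sub(obj.n_contrib),
        )
    if isinstance(obj, DelayNetwork):
        sel = np.ix_(idx, idx)
        return DelayNetwork(tau=obj.tau[sel], coupling=obj.coupling[sel],
                            rois=rois)
    raise TypeError(f"cannot exclude ROIs from {type(obj).__name__}")


def filter_small_diameter(network: GroupNetwork,
                          threshold: float = 1.0) -> GroupNetwork:
    """Drop edges whose mean axon diameter is strictly below ``threshold`` um.

    Mirrors the bundle filter applied after streamline-weight optimisation in
    single-subject pipelines: bundles with implausibly small average
    diameters are treated as spurious.  The comparison is strict, so an edge
    at exactly the threshold is kept.
    """
    if threshold < 0:
        raise DomainError("threshold must be >= 0")
    adjacency = network.adjacency & ~(network.diameter < threshold)

    def _maskout(m):
        return np.where(adjacency, m, 0)

    return GroupNetwork(
        rois=network.rois.copy(),
        adjacency=adjacency,
        length=_maskout(network.length),
        diameter=_maskout(network.diameter),
        gratio=_maskout(network.gratio),
        velocity=_maskout(network.velocity),
        delay=_maskout(network.delay),
        n_contrib=_maskout(network.n_contrib),
    )


def to_delay_network(network: GroupNetwork) -> DelayNetwork:
    """Extract the (tau, coupling) pair a delay-weighted analysis consumes."""
    if np.any(network.delay[network.adjacency] <= 0):
        raise ValidationError("non-positive delay on a retained edge")
    return DelayNetwork(
        tau=np.where(network.adjacency, network.delay, 0.0),
        coupling=network.adjacency.copy(),
        rois=network.rois.copy(),
    )
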