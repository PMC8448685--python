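"""Synthetic multi-subject connectome stacks with ground truth.

Stands in for the MRI/tractography front end: emits per-subject streamline
counts, connection lengths and connection-averaged microstructural weights
(diameter, MTV, f_r, f_csf) with the statistical structure the downstream
analysis assumes —

* 14 subjects over 82 ROIs (34 cortical + 7 subcortical per hemisphere,
  a Desikan-Killiany-sized parcellation without cerebellum/brainstem);
* connection lengths 0.01-0.25 m, right-skewed;
* axon diameters concentrated between 3 and 4 um, with extra spread on
  connections shorter than 0.05 m (short bundles mix fibre populations and
  suffer the strongest tractography partial-volume effects);
* a moderate linear g-ratio-diameter relation, induced *mechanistically* by
  coupling MTV to diameter and deriving g through the volume-fraction
  formulas, so every edge is self-consistent under the closed-form model;
* a near-constant velocity-length trend (velocity inherits the flat
  diameter-length profile).

A second mode constructs stacks whose every edge has a known constant
conduction velocity (up to multiplicative noise), for parameter-recovery
tests of the delay-length regression.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import micro
from .errors import ConfigError, GenerationError
from .network import ConnectomeStack

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "default_roi_table",
    "generate_connectome",
    "generate_constant_velocity_truth",
]

# Shape of the truncated-gamma length distribution and the dilution factor
# between the MTV-diameter correlation and the resulting g-diameter R^2
# (g inherits extra variance from f_r / f_csf noise).  Both frozen from a
# one-off calibration of the generator against its own stated targets.
_LENGTH_GAMMA_SHAPE = 2.4
_LENGTH_GAMMA_SCALE = 0.033
_GD_DILUTION = 0.87


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_subjects: int = 14
    n_rois: int = 82
    subcortical_labels: Optional[list] = None  # derived from ROI table if None
    edge_density: float = 0.25
    length_range: tuple = (0.01, 0.25)
    diameter_mean: float = 3.4      # um
    diameter_sd: float = 0.25       # um
    short_length_extra_sd: float = 0.6   # um, added below short_length_cutoff
    short_length_cutoff: float = 0.05    # m
    gd_coupling: float = 0.43       # target R^2 of g on d
    mtv_mean: float = 0.28
    mtv_sd: float = 0.035
    fr_mean: float = 0.55
    fr_sd: float = 0.05
    fcsf_mean: float = 0.08
    fcsf_sd: float = 0.03
    nos_mean: float = 30.0
    subject_dropout: float = 0.05
    noise_sd_frac: float = 0.02     # multiplicative delay noise, cv mode
    k_rushton: float = micro.DEFAULT_K_RUSHTON
    seed: Optional[int] = None

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing *all* violations."""
        problems = []
        if self.n_rois < 3:
            problems.append("n_rois must be >= 3")
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if not 0 < self.edge_density <= 1:
            problems.append("edge_density must lie in (0, 1]")
        lo, hi = self.length_range
        if not lo < hi:
            problems.append("length_range must satisfy min < max")
        if lo < 0:
            problems.append("length_range min must be >= 0")
        for name in ("gd_coupling", "mtv_mean", "fr_mean", "fcsf_mean",
                     "subject_dropout"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                problems.append(f"{name} must lie in [0, 1]")
        for name in ("diameter_mean", "diameter_sd", "mtv_sd", "fr_sd",
                     "fcsf_sd", "short_length_extra_sd", "nos_mean",
                     "noise_sd_frac", "k_rushton"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class TruthRecord:
    """Edge-level ground truth emitted alongside a synthetic stack."""

    mode: str                      # "empirical" | "constant_velocity"
    v_true: Optional[float]        # m/s, constant-velocity mode only
    diameter: np.ndarray           # (N, N) true edge diameters, um
    gratio: np.ndarray             # (N, N) true edge g-ratios
    velocity: np.ndarray           # (N, N) true edge velocities, m/s

    def as_meta(self) -> dict:
        d = asdict(self)
        d["diameter"] = self.diameter.tolist()
        d["gratio"] = self.gratio.tolist()
        d["velocity"] = self.velocity.tolist()
        return d


def default_roi_table(n_rois: int = 82) -> pd.DataFrame:
    """Fabricated bilateral parcellation: per hemisphere, ~34:7 cortical to
    subcortical split (the Desikan-Killiany proportion), names synthetic."""
    per_hemi = n_rois // 2
    extra = n_rois - 2 * per_hemi
    rows = []
    for hemi, n_h in (("L", per_hemi + extra), ("R", per_hemi)):
        n_sc = max(1, round(n_h * 7 / 41)) if n_h >= 3 else 0
        n_ctx = n_h - n_sc
        for i in range(n_ctx):
            rows.append((f"{hemi}_cortical_{i + 1:02d}", hemi, False))
        for i in range(n_sc):
            rows.append((f"{hemi}_subcortical_{i + 1:02d}", hemi, True))
    return pd.DataFrame(rows, columns=["name", "hemisphere", "is_subcortical"])


def _truncated_gamma_lengths(rng, n, lo, hi):
    """Right-skewed lengths on [lo, hi]: offset gamma, resampled into range."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = lo + rng.gamma(_LENGTH_GAMMA_SHAPE, _LENGTH_GAMMA_SCALE,
                              size=todo.size) * (hi - lo) / 0.24
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _roi_table(cfg: SynthConfig) -> pd.DataFrame:
    rois = default_roi_table(cfg.n_rois)
    if cfg.subcortical_labels is not None:
        unknown = set(cfg.subcortical_labels) - set(rois["name"])
        if unknown:
            raise ConfigError(
                f"subcortical_labels not in ROI table: {sorted(unknown)}")
        rois["is_subcortical"] = rois["name"].isin(cfg.subcortical_labels)
    return rois


def _sample_group_edges(rng, cfg):
    n = cfg.n_rois
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < cfg.edge_density
    return iu[present], ju[present]


def _edge_matrix(n, iu, ju, values):
    m = np.zeros((n, n))
    m[iu, ju] = values
    m[ju, iu] = values
    return m


def _subject_weights(rng, cfg, iu, ju, edge, jitter=True):
    """Expand edge-level truth into per-subject symmetric weight matrices."""
    n, n_sub, n_e = cfg.n_rois, cfg.n_subjects, iu.size
    base_count = rng.gamma(2.0, cfg.nos_mean / 2.0, size=n_e)
    weights = {w: np.zeros((n_sub, n, n)) for w in
               ("count", "length", "diameter", "mtv", "fr", "fcsf")}
    for s in range(n_sub):
        count = rng.poisson(base_count).astype(float)
        count[rng.random(n_e) < cfg.subject_dropout] = 0.0
        present = count > 0
        length = edge["length"] * (1 + 0.02 * rng.standard_normal(n_e))
        if jitter:
            diameter = edge["diameter"] * (1 + 0.015 * rng.standard_normal(n_e))
            mtv = np.clip(edge["mtv"] + rng.normal(0, 0.01, n_e), 0.02, 0.95)
            fr = np.clip(edge["fr"] + rng.normal(0, 0.015, n_e), 0.02, 0.98)
            fcsf = np.clip(edge["fcsf"] + rng.normal(0, 0.008, n_e), 0.0, 0.5)
        else:
            diameter, mtv, fr, fcsf = (edge["diameter"], edge["mtv"],
                                       edge["fr"], edge["fcsf"])
        vals = {"count": count, "length": np.clip(length, 1e-4, None),
                "diameter": np.clip(diameter, 0.05, None),
                "mtv": mtv, "fr": fr, "fcsf": fcsf}
        for w, v in vals.items():
            weights[w][s] = _edge_matrix(n, iu, ju, np.where(present, v, 0.0))
    return weights


def generate_connectome(config: SynthConfig | None = None,
                        ) -> tuple[ConnectomeStack, TruthRecord]:
    """Generate an empirical-mode stack; same seed gives identical output."""
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_rois
    rois = _roi_table(cfg)
    iu, ju = _sample_group_edges(rng, cfg)
    if iu.size == 0:
        raise GenerationError("edge sampling produced no edges; raise "
                              "edge_density or n_rois")
    n_e = iu.size
    lo, hi = cfg.length_range
    length = _truncated_gamma_lengths(rng, n_e, lo, hi)

    sd = np.where(length < cfg.short_length_cutoff,
                  cfg.diameter_sd + cfg.short_length_extra_sd, cfg.diameter_sd)
    diameter = np.clip(rng.normal(cfg.diameter_mean, sd), 0.3, None)

    # couple MTV (negatively) to diameter so that g, derived through the
    # AVF/Stikov formulas, correlates positively with d at about the target
    # R^2 once f_r / f_csf noise has diluted it
    r_c = min(0.99, np.sqrt(cfg.gd_coupling) / _GD_DILUTION)
    z = (diameter - diameter.mean()) / max(diameter.std(), 1e-9)
    eps = rng.standard_normal(n_e)
    mtv = cfg.mtv_mean + cfg.mtv_sd * (-r_c * z + np.sqrt(1 - r_c ** 2) * eps)
    mtv = np.clip(mtv, 0.05, 0.6)
    fr = np.clip(rng.normal(cfg.fr_mean, cfg.fr_sd, n_e), 0.05, 0.95)
    fcsf = np.clip(rng.normal(cfg.fcsf_mean, cfg.fcsf_sd, n_e), 0.0, 0.35)

    avf = micro.compute_avf(mtv, fcsf, fr)
    g = micro.compute_gratio(mtv, avf)
    v = micro.rushton_velocity(diameter, g, cfg.k_rushton)

    edge = {"length": length, "diameter": diameter, "mtv": mtv,
            "fr": fr, "fcsf": fcsf}
    weights = _subject_weights(rng, cfg, iu, ju, edge, jitter=True)
    truth = TruthRecord(
        mode="empirical", v_true=None,
        diameter=_edge_matrix(n, iu, ju, diameter),
        gratio=_edge_matrix(n, iu, ju, g),
        velocity=_edge_matrix(n, iu, ju, v),
    )
    subjects = [f"sub-{s + 1:02d}" for s in range(cfg.n_subjects)]
    stack = ConnectomeStack(rois=rois, subjects=subjects, weights=weights,
                            meta={"mode": "empirical"})
    return stack, truth


def generate_constant_velocity_truth(
    config: SynthConfig | None = None, v_true: float = 13.42,
) -> tuple[ConnectomeStack, TruthRecord]:
    """Stack whose every edge conducts at ``v_true`` m/s up to noise.

    Per edge the generator samples a diameter within 4 SD of the configured
    mean, perturbs the target velocity by multiplicative lognormal noise of
    fractional SD ``noise_sd_frac``, then *solves* the Rushton and Stikov
    equations backwards for the g-ratio and MTV that reproduce that velocity
    exactly (f_r and f_csf held at their configured means).  Subject-level
    microstructure is therefore noiseless; only lengths carry the usual 2%
    anatomical jitter, and delay/length = velocity per subject by
    construction.
    """
    cfg = config or SynthConfig()
    cfg.validate()
    if v_true <= 0:
        raise GenerationError("v_true must be > 0")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_rois
    rois = _roi_table(cfg)
    iu, ju = _sample_group_edges(rng, cfg)
    n_e = iu.size
    lo, hi = cfg.length_range
    length = _truncated_gamma_lengths(rng, n_e, lo, hi)

    d_hi = cfg.diameter_mean + 4 * cfg.diameter_sd
    g_at_dhi = np.exp(-((v_true / (cfg.k_rushton * d_hi * 1e-6)) ** 2))
    if g_at_dhi < 1e-8:
        raise GenerationError(
            f"v_true={v_true} m/s is not achievable with g in (0, 1) and a "
            f"diameter within 4 SD of {cfg.diameter_mean} um"
        )

    # truncated-normal diameters within 4 SD (and positive)
    d_lo = max(cfg.diameter_mean - 4 * cfg.diameter_sd, 0.1)
    diameter = np.empty(n_e)
    todo = np.arange(n_e)
    while todo.size:
        draw = rng.normal(cfg.diameter_mean, cfg.diameter_sd, todo.size)
        ok = (draw >= d_lo) & (draw <= d_hi)
        diameter[todo[ok]] = draw[ok]
        todo = todo[~ok]

    v_edge = v_true * np.exp(
        rng.normal(0.0, cfg.noise_sd_frac, n_e)) if cfg.noise_sd_frac > 0 \
        else np.full(n_e, float(v_true))
    # invert Rushton for g, then Stikov/AVF for MTV
    g = np.exp(-((v_edge / (cfg.k_rushton * diameter * 1e-6)) ** 2))
    q = 1.0 / g ** 2 - 1.0
    c = (1.0 - cfg.fcsf_mean) * cfg.fr_mean
    mtv = q * c / (1.0 + q * c)

    edge = {"length": length, "diameter": diameter, "mtv": mtv,
            "fr": np.full(n_e, cfg.fr_mean),
            "fcsf": np.full(n_e, cfg.fcsf_mean)}
    weights = _subject_weights(rng, cfg, iu, ju, edge, jitter=False)
    truth = TruthRecord(
        mode="constant_velocity", v_true=float(v_true),
        diameter=_edge_matrix(n, iu, ju, diameter),
        gratio=_edge_matrix(n, iu, ju, g),
        velocity=_edge_matrix(n, iu, ju, v_edge),
    )
    subjects = [f"sub-{s + 1:02d}" for s in range(cfg.n_subjects)]
    stack = ConnectomeStack(rois=rois, subjects=subjects, weights=weights,
                            meta={"mode": "constant_velocity",
                                  "v_true": float(v_true)})
    return stack, truth
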