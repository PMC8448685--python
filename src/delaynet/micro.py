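"""Closed-form microstructure relations for myelinated axons.

Maps MRI-derived tissue quantities to the g-ratio, conduction velocity and
conduction delay of a white-matter connection:

* macromolecular tissue volume  MTV = 1 - PD/PD_f
* axonal volume fraction        AVF = (1 - MTV)(1 - f_csf) f_r
* g-ratio (Stikov)              g   = sqrt(1 / (1 + MTV/AVF))
* conduction velocity (Rushton) v   = k * d * sqrt(-ln g)
* conduction delay              tau = length / v

Diameters are micrometres at the interface (converted to metres inside the
velocity formula so that, with ``k`` in 1/s, velocities come out in m/s);
lengths are metres and delays seconds.

All operations broadcast elementwise over arrays.  An optional boolean
``where`` mask restricts both domain validation and evaluation to masked
entries — entries outside the mask are returned as 0 and never touched, so
applying the formulas to a sparse symmetric matrix preserves its sparsity
pattern, symmetry and zero diagonal.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

#: Rushton proportionality constant between d*sqrt(-ln g) and velocity, 1/s.
DEFAULT_K_RUSHTON = 7e6

__all__ = [
    "DEFAULT_K_RUSHTON",
    "compute_mtv",
    "compute_avf",
    "compute_gratio",
    "rushton_velocity",
    "conduction_delay",
]


def _prepare(where, *arrays):
    """Broadcast inputs, return (broadcast arrays, flat selection mask)."""
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    if where is None:
        shape = np.broadcast_shapes(*(a.shape for a in arrays))
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(where, dtype=bool)
        shape = np.broadcast_shapes(mask.shape, *(a.shape for a in arrays))
        mask = np.broadcast_to(mask, shape)
    arrays = [np.broadcast_to(a, shape) for a in arrays]
    return arrays, mask


def _check(mask, condition, message):
    """Raise DomainError if ``condition`` fails anywhere inside the mask."""
    bad = mask & ~np.asarray(condition, dtype=bool)
    if np.any(bad):
        raise DomainError(message)


def compute_mtv(pd, pd_f, *, where=None):
    """Macromolecular tissue volume fraction, ``1 - pd/pd_f``.

    Parameters
    ----------
    pd : array_like
        Proton density (arbitrary units, ``0 <= pd <= pd_f``).
    pd_f : array_like
        Proton density of free water (same units, ``> 0``).
    where : array_like of bool, optional
        Evaluate (and validate) only where True; other entries are 0.
    """
    (pd, pd_f), mask = _prepare(where, pd, pd_f)
    _check(mask, pd_f > 0, "pd_f must be > 0")
    _check(mask, pd >= 0, "pd must be >= 0")
    _check(mask, pd <= pd_f, "pd must not exceed pd_f")
    out = np.zeros(mask.shape)
    out[mask] = 1.0 - pd[mask] / pd_f[mask]
    return out if out.ndim else float(out)


def compute_avf(mtv, f_csf, f_r, *, where=None):
    """Axonal volume fraction, ``(1 - mtv) * (1 - f_csf) * f_r``.

    All three inputs are dimensionless fractions in [0, 1]; so is the result.
    """
    (mtv, f_csf, f_r), mask = _prepare(where, mtv, f_csf, f_r)
    for name, arr in (("mtv", mtv), ("f_csf", f_csf), ("f_r", f_r)):
        _check(mask, (arr >= 0) & (arr <= 1), f"{name} must lie in [0, 1]")
    out = np.zeros(mask.shape)
    out[mask] = (1.0 - mtv[mask]) * (1.0 - f_csf[mask]) * f_r[mask]
    return out if out.ndim else float(out)


def compute_gratio(mtv, avf, *, where=None):
    """Aggregate g-ratio from myelin (MTV) and axonal (AVF) volume fractions.

    ``g = sqrt(1 / (1 + mtv/avf))`` — in (0, 1], strictly decreasing in
    ``mtv`` at fixed ``avf`` (more myelin, relatively thicker sheath), equal
    to 1 when ``mtv == 0``.  Undefined for ``avf <= 0``.
    """
    (mtv, avf), mask = _prepare(where, mtv, avf)
    _check(mask, mtv >= 0, "mtv must be >= 0")
    _check(mask, avf > 0, "avf must be > 0 (g-ratio undefined otherwise)")
    out = np.zeros(mask.shape)
    # sqrt(1/(1 + mtv/avf)) rewritten to stay finite for tiny avf
    out[mask] = np.sqrt(avf[mask] / (avf[mask] + mtv[mask]))
    return out if out.ndim else float(out)


def rushton_velocity(d, g, k_rushton=DEFAULT_K_RUSHTON, *, where=None,
                     clamp_g=False):
    """Conduction velocity of a myelinated axon, ``k * d * sqrt(-ln g)``.

    Parameters
    ----------
    d : array_like
        Inner axon diameter in micrometres (``>= 0``); converted to metres
        internally so the result is in m/s.
    g : array_like
        g-ratio in (0, 1].  ``g == 1`` (no myelin) yields velocity 0 by the
        formula; pass ``clamp_g=True`` to clamp such entries to ``1 - 1e-12``
        instead when a strictly positive velocity is required downstream.
    k_rushton : float
        Proportionality constant in 1/s (default 7e6).

    Notes
    -----
    With d ~ 3 um and g ~ 0.7 this gives ~12.5 m/s, the magnitude expected
    for large myelinated fibres.
    """
    (d, g), mask = _prepare(where, d, g)
    _check(mask, d >= 0, "diameter d must be >= 0")
    _check(mask, (g > 0) & (g <= 1), "g-ratio must lie in (0, 1]")
    gm = g[mask]
    if clamp_g:
        gm = np.minimum(gm, 1.0 - 1e-12)
    out = np.zeros(mask.shape)
    out[mask] = k_rushton * (d[mask] * 1e-6) * np.sqrt(-np.log(gm))
    return out if out.ndim else float(out)


def conduction_delay(length, v, *, where=None):
    """Conduction delay ``length / v`` in seconds.

    ``length`` in metres (``>= 0``), ``v`` in m/s (``> 0``).
    """
    (length, v), mask = _prepare(where, length, v)
    _check(mask, length >= 0, "length must be >= 0")
    _check(mask, v > 0, "velocity must be > 0 (delay undefined otherwise)")
    out = np.zeros(mask.shape)
    out[mask] = length[mask] / v[mask]
    return out if out.ndim else float(out)
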