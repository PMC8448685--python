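"""statsmodels-style front end: a model built from a connectome stack whose
``fit()`` returns a results object carrying the group network, the
delay-length regression and everything downstream (path comparison,
Kuramoto sweeps, plots)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import graph as graph_mod
from . import kuramoto as km
from . import micro, regress
from .network import (
    ConnectomeStack,
    DelayNetwork,
    GroupNetwork,
    exclude_rois,
    filter_small_diameter,
    group_average,
    to_delay_network,
)
from .synthetic import SynthConfig, generate_connectome

__all__ = ["ConductionDelayModel", "ConductionDelayResults", "PathComparison"]


class ConductionDelayModel:
    """Whole-brain conduction-delay model over a multi-subject connectome.

    Given per-subject connectivity matrices (streamline count, length and
    connection-averaged microstructure), the model derives per-edge g-ratios
    and Rushton conduction velocities, assembles the group network under the
    streamline-count inclusion rule, and fits the delay-length relation whose
    reciprocal slope is the network's implied constant conduction velocity.

    Parameters
    ----------
    stack : ConnectomeStack
        Input data (e.g. from :func:`delaynet.synthetic.generate_connectome`
        or :meth:`ConnectomeStack.from_dir`).
    k_rushton : float
        Rushton proportionality constant, 1/s.
    min_count, min_subjects : int
        Group inclusion rule: an edge is retained iff strictly more than
        ``min_count`` streamlines in at least ``min_subjects`` subjects.
    delay_aggregation : {"subject_mean", "ratio_of_means"}
        How subject delays are combined into the group delay.
    diameter_threshold : float, optional
        If given, drop group edges with mean diameter strictly below this
        value (um) after averaging.
    exclude : list of str, optional
        ROI names removed from the stack before any computation.
    through_origin : bool
        Force the delay-length regression through the origin.

    Examples
    --------
    >>> from delaynet import ConductionDelayModel, SynthConfig
    >>> model = ConductionDelayModel.from_synthetic(SynthConfig(seed=1))
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(self, stack: ConnectomeStack, *,
                 k_rushton: float = micro.DEFAULT_K_RUSHTON,
                 min_count: int = 4, min_subjects: int = 9,
                 delay_aggregation: str = "subject_mean",
                 diameter_threshold: Optional[float] = None,
                 exclude: Optional[list] = None,
                 through_origin: bool = False):
        if exclude:
            stack = exclude_rois(stack, exclude)
        self.stack = stack
        self.k_rushton = k_rushton
        self.min_count = min_count
        self.min_subjects = min_subjects
        self.delay_aggregation = delay_aggregation
        self.diameter_threshold = diameter_threshold
        self.through_origin = through_origin

    @classmethod
    def from_stack_dir(cls, path, **kwargs) -> "ConductionDelayModel":
        return cls(ConnectomeStack.from_dir(path), **kwargs)

    @classmethod
    def from_synthetic(cls, config: Optional[SynthConfig] = None,
                       **kwargs) -> "ConductionDelayModel":
        stack, _ = generate_connectome(config or SynthConfig())
        return cls(stack, **kwargs)

    def fit(self) -> "ConductionDelayResults":
        group = group_average(
            self.stack, self.min_count, self.min_subjects,
            k_rushton=self.k_rushton,
            delay_aggregation=self.delay_aggregation,
        )
        if self.diameter_threshold is not None:
            group = filter_small_diameter(group, self.diameter_threshold)
        edges = group.edge_table()
        regression = regress.fit_delay_length(
            edges["delay_s"], edges["length_m"],
            through_origin=self.through_origin,
        )
        return ConductionDelayResults(model=self, group=group, edges=edges,
                                      regression=regression)


@dataclass
class PathComparison:
    """Graph-level comparison of estimated vs constant-velocity delays."""

    sp_estimated: np.ndarray
    sp_constant: np.ndarray
    percent_diff: np.ndarray
    bc_estimated: np.ndarray
    bc_constant: np.ndarray
    blocks: pd.DataFrame


class ConductionDelayResults:
    """Fit results: group network, regression and downstream analyses.

    Attributes
    ----------
    group : GroupNetwork
        Group-averaged network after inclusion/exclusion rules.
    edges : pandas.DataFrame
        One row per retained undirected edge with all mean weights.
    regression : RegressionSummary
        Delay-length OLS; ``regression.implied_velocity`` is the constant
        velocity (m/s) the network's delays collectively imply.
    """

    def __init__(self, model: ConductionDelayModel, group: GroupNetwork,
                 edges: pd.DataFrame, regression: regress.RegressionSummary):
        self.model = model
        self.group = group
        self.edges = edges
        self.regression = regression

    # ---- headline scalars ------------------------------------------------
    @property
    def implied_velocity(self) -> Optional[float]:
        return self.regression.implied_velocity

    def diameter_band_fraction(self, lo: float = 3.0, hi: float = 4.0) -> float:
        """Fraction of edges with mean diameter inside [lo, hi] um."""
        return regress.band_fraction(self.edges["diameter_um"], lo, hi)

    def gratio_diameter_r_squared(self) -> float:
        """R^2 of the linear g-ratio ~ diameter relation across edges."""
        _, _, r2 = regress.linear_fit(self.edges["diameter_um"],
                                      self.edges["gratio"])
        return r2

    def velocity_diameter_pearson(self) -> float:
        """Pearson r between edge velocity and edge diameter."""
        return regress.pearson(self.edges["velocity_m_per_s"],
                               self.edges["diameter_um"])

    # ---- delay networks --------------------------------------------------
    def delay_network(self) -> DelayNetwork:
        """Estimated-delay network (tau from the microstructural model)."""
        return to_delay_network(self.group)

    def constant_velocity_network(self,
                                  v_const: Optional[float] = None
                                  ) -> DelayNetwork:
        """Constant-velocity approximation on the same edge set.

        ``v_const`` defaults to the implied velocity from the delay-length
        regression.
        """
        v = self.implied_velocity if v_const is None else v_const
        tau = regress.constant_velocity_delays(self.group.length, v,
                                               self.group.adjacency)
        return DelayNetwork(tau=tau, coupling=self.group.adjacency.copy(),
                            rois=self.group.rois.copy())

    # ---- graph comparison ------------------------------------------------
    def compare_paths(self, v_const: Optional[float] = None,
                      tie_tol: float = graph_mod.DEFAULT_TIE_TOL
                      ) -> PathComparison:
        net_est = self.delay_network()
        net_cv = self.constant_velocity_network(v_const)
        pa_est = graph_mod.path_analysis(net_est, tie_tol)
        pa_cv = graph_mod.path_analysis(net_cv, tie_tol)
        diff = graph_mod.compare_path_matrices(pa_est.sp, pa_cv.sp)
        blocks = graph_mod.block_summary(diff, self.group.rois)
        return PathComparison(
            sp_estimated=pa_est.sp, sp_constant=pa_cv.sp, percent_diff=diff,
            bc_estimated=pa_est.bc, bc_constant=pa_cv.bc, blocks=blocks,
        )

    # ---- Kuramoto --------------------------------------------------------
    def kuramoto_sweep(self, config: Optional[km.KuramotoConfig] = None,
                       condition: str = "estimated",
                       v_const: Optional[float] = None,
                       progress=None) -> km.SweepResult:
        """Coupling sweep under either delay condition.

        ``condition`` is ``"estimated"`` (microstructure-derived delays) or
        ``"constant"`` (constant-velocity delays at ``v_const``, default the
        implied velocity).
        """
        if condition == "estimated":
            net = self.delay_network()
        elif condition == "constant":
            net = self.constant_velocity_network(v_const)
        else:
            raise ValueError(f"unknown condition '{condition}'")
        return km.sweep(net, config or km.KuramotoConfig(), progress=progress)

    # ---- reporting -------------------------------------------------------
    def summary(self) -> str:
        g = self.group
        reg = self.regression
        v = ("undefined" if reg.implied_velocity is None
             else f"{reg.implied_velocity:9.4f} m/s")
        lines = [
            "Conduction delay network results",
            "=" * 48,
            f"ROIs                     {g.n_rois:9d}",
            f"retained edges           {g.n_edges:9d}",
            f"mean length              {self.edges['length_m'].mean():9.4f} m",
            f"mean diameter            {self.edges['diameter_um'].mean():9.4f} um",
            f"mean g-ratio             {self.edges['gratio'].mean():9.4f}",
            f"mean velocity            {self.edges['velocity_m_per_s'].mean():9.4f} m/s",
            f"mean delay               {self.edges['delay_s'].mean() * 1e3:9.4f} ms",
            "-" * 48,
            "delay ~ length (OLS)",
            f"  slope                  {reg.slope:9.5f} s/m",
            f"  intercept              {reg.intercept * 1e3:9.5f} ms",
            f"  R^2                    {reg.r_squared:9.4f}",
            f"  implied velocity       {v}",
            "-" * 48,
            f"diameter in [3, 4] um    {100 * self.diameter_band_fraction():8.2f} %",
            f"g-ratio ~ diameter R^2   {self.gratio_diameter_r_squared():9.4f}",
            f"velocity-diameter r      {self.velocity_diameter_pearson():9.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<ConductionDelayResults: {self.group.n_rois} ROIs, "
                f"{self.group.n_edges} edges, "
                f"R^2={self.regression.r_squared:.3f}>")

    # ---- plotting --------------------------------------------------------
    def plot_delay_length(self, ax=None):
        """Scatter of edge delays (ms) against lengths (m) with the OLS line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.edges["length_m"]
        ax.scatter(x, self.edges["delay_s"] * 1e3, s=8, alpha=0.5)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, (self.regression.slope * xs + self.regression.intercept)
                * 1e3, "k-", lw=1)
        ax.set_xlabel("connection length (m)")
        ax.set_ylabel("conduction delay (ms)")
        return ax
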