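"""Model/Results front end for the XlnR regulon analysis.

:class:`XlnRRegulonModel` is constructed from time-course data (lists of
:class:`~xlnrdyn.data.TimeCourse` or a tidy DataFrame); ``fit()`` runs
the sequential wild-type -> mutant estimation protocol and returns an
:class:`XlnRRegulonResults` carrying per-gene kinetic estimates, their
multi-start coefficients of variation, goal-function values,
de-repression fold-changes, and a ``summary()`` table. Simulation,
profile classification, clustering and plotting hang off the two
objects.

Example
-------
>>> from xlnrdyn.synthetic import generate_regulon, WT_DESIGN
>>> from xlnrdyn.model import XlnRRegulonModel
>>> ds = generate_regulon(WT_DESIGN, seed=7)
>>> model = XlnRRegulonModel(wt_data=[tc for tc in ds.timecourses
...                                   if tc.gene != "xlnR"])
>>> res = model.fit(seed=7)
>>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering, profiles
from .data import TimeCourse, frame_to_timecourses
from .estimation import (
    FitOptions,
    ProtocolConfig,
    ProtocolResult,
    KineticParameters,
    default_input,
    predict_timecourse,
    sensitivity_ranking,
    two_stage_protocol,
)

__all__ = ["XlnRRegulonModel", "XlnRRegulonResults"]


class XlnRRegulonModel:
    """Antagonistic-Hill kinetic model of an XlnR target-gene panel.

    Parameters
    ----------
    wt_data, mt_data
        Time courses of the wild type and (optionally) the CreA mutant;
        each gene needs both induction conditions (1 and 50 mM).
    config
        Protocol configuration (initialization, optimizer options,
        whether the mutant stage also frees k_id).
    """

    def __init__(
        self,
        wt_data: Sequence[TimeCourse],
        mt_data: Sequence[TimeCourse] = (),
        config: ProtocolConfig | None = None,
    ):
        self.wt_data = list(wt_data)
        self.mt_data = list(mt_data)
        self.config = config or ProtocolConfig()
        if not self.wt_data:
            raise ValueError("wt_data must contain at least one time course")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: ProtocolConfig | None = None
    ) -> "XlnRRegulonModel":
        """Build from a tidy table (gene, strain, xylose_mM, time_h,
        mean_expr, sd_expr, n_rep); the constitutive xlnR row is dropped
        from the fitted panel automatically."""
        tcs = [tc for tc in frame_to_timecourses(df) if tc.gene != "xlnR"]
        return cls(
            wt_data=[tc for tc in tcs if tc.strain == "Wt"],
            mt_data=[tc for tc in tcs if tc.strain == "Mt"],
            config=config,
        )

    def fit(self, seed: int | None = None, n_restarts: int | None = None
            ) -> "XlnRRegulonResults":
        """Run the two-stage protocol; deterministic given the seed."""
        cfg = self.config
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        if n_restarts is not None:
            cfg = replace(cfg, options=replace(cfg.options, n_restarts=n_restarts))
        proto = two_stage_protocol(self.wt_data, self.mt_data, cfg)
        return XlnRRegulonResults(self, proto)

    def sensitivity(self, params: KineticParameters | None = None) -> pd.Series:
        """Finite-difference sensitivity ranking justifying the
        shared-block (theta1) fixing."""
        times = self.wt_data[0].times
        return sensitivity_ranking(params or self.config.init, times)


class XlnRRegulonResults:
    """Estimation results for a fitted regulon panel."""

    def __init__(self, model: XlnRRegulonModel, protocol: ProtocolResult):
        self.model = model
        self.protocol = protocol

    # -- accessors ----------------------------------------------------------
    @property
    def theta1_bar(self) -> dict[str, float]:
        """Averaged-and-fixed shared block (K_on, K_off, k1, k2)."""
        return self.protocol.theta1_bar

    @property
    def wt(self):
        return self.protocol.wt

    @property
    def mt(self):
        return self.protocol.mt

    @property
    def fold_changes(self) -> dict[str, float]:
        """Per-gene de-repression fold-change lambda = k_is_Mt/k_is_Wt."""
        return self.protocol.fold_changes

    def params_frame(self) -> pd.DataFrame:
        return self.protocol.params_frame()

    def predict(self, gene: str, condition: float, strain: str = "Wt",
                times: np.ndarray | None = None) -> np.ndarray:
        """Fitted-model transcript trajectory for one gene/condition."""
        fr = (self.wt if strain == "Wt" else self.mt)[gene]
        tc = next(tc for tc in (self.model.wt_data if strain == "Wt"
                                else self.model.mt_data)
                  if tc.gene == gene and tc.condition == condition)
        t = tc.times if times is None else np.asarray(times, dtype=float)
        return predict_timecourse(fr.theta_hat, default_input(condition), t,
                                  strain=strain, x_i0=float(tc.mean[0]))

    def classify(self, **kwargs) -> pd.DataFrame:
        """Qualitative class (C1-C4) of every fitted time course."""
        cfg = profiles.ClassifierConfig(**kwargs) if kwargs else profiles.ClassifierConfig()
        return profiles.classification_table(
            self.model.wt_data + self.model.mt_data, cfg)

    def cluster(self, strain: str = "Wt", condition: float = 1.0,
                config: clustering.ClusterConfig | None = None
                ) -> clustering.ClusteringResult:
        """DTW + average-linkage clustering of one condition's profiles."""
        data = self.model.wt_data if strain == "Wt" else self.model.mt_data
        sel = [tc for tc in data if tc.condition == condition]
        return clustering.cluster_genes(sel, config or clustering.ClusterConfig())

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable estimation report."""
        lines = []
        lines.append("XlnR regulon kinetic fit (two-stage protocol)")
        lines.append("=" * 60)
        lines.append(
            f"wild-type genes: {len(self.wt)}   mutant genes: {len(self.mt)}"
        )
        t1 = "  ".join(f"{k}={v:.4g}" for k, v in self.theta1_bar.items())
        lines.append(f"fixed shared block  {t1}")
        lines.append("-" * 60)
        df = self.params_frame()
        cols = ["gene", "strain", "k_is_Wt", "k_is_Mt", "K_i1", "K_i2_Wt",
                "K_i2_Mt", "k_id", "J_comb"]
        cols = [c for c in cols if c in df.columns]
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(df[cols].to_string(index=False))
        if self.fold_changes:
            lines.append("-" * 60)
            for g, lam in sorted(self.fold_changes.items()):
                lines.append(f"lambda({g}) = k_is_Mt/k_is_Wt = {lam:.3g}")
        return "\n".join(lines)

    def plot_fit(self, gene: str, strain: str = "Wt", ax=None):
        """Data (with SD band) and fitted trajectories for one gene."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.wt_data if strain == "Wt" else self.model.mt_data
        for tc in (t for t in data if t.gene == gene):
            pts = ax.plot(tc.times, tc.mean, "o", ms=4,
                          label=f"{tc.condition:g} mM data")
            color = pts[0].get_color()
            ax.fill_between(tc.times, tc.mean - tc.sd, tc.mean + tc.sd,
                            alpha=0.2, color=color)
            t_dense = np.linspace(0, tc.times[-1], 200)
            ax.plot(t_dense, self.predict(gene, tc.condition, strain, t_dense),
                    "-", color=color, label=f"{tc.condition:g} mM fit")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("normalized expression (a.u.)")
        ax.set_title(f"{gene} ({strain})")
        ax.legend(fontsize=8)
        return ax
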