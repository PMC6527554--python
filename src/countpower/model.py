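"""Model/Results interface tying the analysis stages together.

:class:`DEPowerModel` is constructed from a count matrix and a sample
design; :meth:`DEPowerModel.fit` runs expression filtering, TMM
normalization, qCML dispersion estimation, differential expression (exact
test, or quasi-likelihood GLM when covariates are given), gene-wise
FDR-adjusted power, triage, and signature construction, returning a
:class:`DEPowerResults` that carries all the tables plus a text
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnalysisConfig, CountDataError, CountMatrix, SampleDesign, validate_dataset
from . import normalize as _normalize_mod
from .normalize import NormalizationResult, filter_expressed as _filter_expressed, normalize as _normalize
from .dispersion import DispersionEstimates, estimate_dispersion
from .power import genewise_power, power_curve, sample_size
from .de import Signature, build_signature, exact_test, glm_ql_test, ma_data, triage

__all__ = ["DEPowerModel", "DEPowerResults"]


class DEPowerModel:
    """Power-aware two-group differential expression model.

    Parameters
    ----------
    counts, design
        The dataset; sample sets must agree.
    comparison
        Pair of group labels ``(reference, treatment)``; log fold changes
        are treatment over reference.
    covariates
        Optional covariate names (e.g. ``["replicate"]``); their presence
        switches the test from the exact test to the QL GLM.
    config
        Cutoffs and parameters; defaults are sensible for bulk RNA-seq.
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: SampleDesign,
        comparison: tuple[str, str],
        covariates: list[str] | None = None,
        config: AnalysisConfig | None = None,
    ):
        validate_dataset(counts, design)
        self.config = (config or AnalysisConfig()).with_(comparison=tuple(comparison))
        self.comparison = design.resolve_comparison(tuple(comparison))
        self.covariates = list(covariates or [])
        self.counts = counts
        self.design = design

    @classmethod
    def from_files(
        cls,
        counts_path,
        design_path,
        comparison: tuple[str, str],
        covariates: list[str] | None = None,
        config: AnalysisConfig | None = None,
    ) -> "DEPowerModel":
        from .io import read_counts, read_design

        return cls(
            read_counts(counts_path), read_design(design_path), comparison, covariates, config
        )

    def fit(self, prior_df: float = 10.0) -> "DEPowerResults":
        cm_all, sd = self.counts, self.design
        keep = _filter_expressed(cm_all, sd, self.comparison)
        comp_samples = sd.comparison_samples(self.comparison)
        cm = cm_all.subset_genes(keep).subset_samples(comp_samples)
        sd_sub = SampleDesign(
            comp_samples,
            {s: sd.group[s] for s in comp_samples},
            {k: {s: v[s] for s in comp_samples if s in v} for k, v in sd.covariates.items()},
        )
        norm = _normalize(cm)
        disp = estimate_dispersion(cm, sd_sub, self.comparison, prior_df=prior_df)
        if self.covariates:
            de = glm_ql_test(cm, sd_sub, self.comparison, self.covariates, disp)
        else:
            de = exact_test(cm, sd_sub, self.comparison, disp)
        det = genewise_power(
            cm, sd_sub, self.comparison, disp, self.config, log2cpm=norm.log2cpm
        )
        labels, counts_by_label = triage(de, det, self.config)
        sig = build_signature(de, det, self.config)
        return DEPowerResults(
            model=self,
            filtered=cm,
            normalization=norm,
            dispersion=disp,
            de=de,
            detectability=det,
            triage_labels=labels,
            triage_counts=counts_by_label,
            signature=sig,
        )


@dataclass
class DEPowerResults:
    """Fitted tables and diagnostics of a :class:`DEPowerModel`."""

    model: DEPowerModel
    filtered: CountMatrix
    normalization: NormalizationResult
    dispersion: DispersionEstimates
    de: pd.DataFrame
    detectability: pd.DataFrame
    triage_labels: pd.Series
    triage_counts: dict[str, int]
    signature: Signature

    @property
    def n_genes(self) -> int:
        return self.filtered.n_genes

    def ma_data(self) -> pd.DataFrame:
        return ma_data(self.de, self.model.config.de_fdr_cutoff)

    def power_curve(self, n_range=range(2, 11)) -> list[tuple[int, float]]:
        """Single-gene power curve at the dataset's average depth (library
        size in millions) and common BCOV."""
        cfg = self.model.config
        mu = float(np.mean(self.filtered.library_sizes()) / 1e6)
        return power_curve(cfg.fold_change, cfg.alpha, mu, self.dispersion.bcov_common, n_range)

    def sample_size(self, target_power: float = 0.8) -> int:
        cfg = self.model.config
        mu = float(np.mean(self.filtered.library_sizes()) / 1e6)
        return sample_size(cfg.fold_change, cfg.alpha, mu, self.dispersion.bcov_common, target_power)

    def plot_ma(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        d = self.ma_data()
        ax.scatter(d["mean_log2cpm"], d["log2_fc"], s=4, c=np.where(d["significant"], "red", "gray"))
        ax.set_xlabel("mean log2 CPM")
        ax.set_ylabel("log2 fold change")
        return ax

    def plot_detectability(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        d = self.detectability
        ax.scatter(d["log2cpm"], d["bcov"], s=4, c=np.where(d["detectable"], "tab:blue", "tab:orange"))
        ax.set_xlabel("mean log2 CPM")
        ax.set_ylabel("BCOV")
        return ax

    def summary(self) -> str:
        cfg = self.model.config
        a, b = self.model.comparison
        mu = float(np.mean(self.filtered.library_sizes()) / 1e6)
        curve = self.power_curve(range(2, 5))
        lines = [
            "Power-aware differential expression",
            "=" * 51,
            f"comparison:            {b} vs {a}"
            + (f"  (covariates: {', '.join(self.model.covariates)})" if self.model.covariates else ""),
            f"test:                  {self.de.attrs['method']}",
            f"genes analyzed:        {self.n_genes} (of {self.model.counts.n_genes} after expression filter)",
            f"average depth:         {mu:.2f} million reads",
            f"common dispersion:     {self.dispersion.common:.4f}  (BCOV {self.dispersion.bcov_common:.3f})",
            f"alpha* (FDR {cfg.fdr_level:g}, pi1 {cfg.true_positive_fraction:g}): "
            f"{self.detectability.attrs['alpha_star']:.3e}",
            "single-gene power:     "
            + "  ".join(f"n={n}: {p:.2f}" for n, p in curve),
            f"n for {0.8:.0%} power:      {self._safe_sample_size()}",
            "-" * 51,
            f"DE (FDR < {cfg.de_fdr_cutoff:g}):         {self.triage_counts['DE']}",
            f"NDE & detectable:      {self.triage_counts['NDE_DT']}",
            f"NDE & not detectable:  {self.triage_counts['NDE_NDT']}",
            f"signature genes (FDR < {cfg.signature_fdr_cutoff:g} or power >= "
            f"{cfg.signature_power_cutoff:g}): {len(self.signature)}",
        ]
        return "\n".join(lines)

    def _safe_sample_size(self) -> str:
        try:
            return str(self.sample_size(0.8))
        except CountDataError:
            return "not reachable (n <= 1000)"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<DEPowerResults: {self.n_genes} genes, {self.triage_counts}>"
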