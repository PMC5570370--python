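"""Model/Results interface over the classification pipeline.

:class:`HsfMirnaModel` wraps a count matrix plus sample sheet for the 2x2
knockdown x heat-shock design; :meth:`HsfMirnaModel.fit` runs detection
filtering, depth normalization, the five contrasts (C1, C2, C3 each vs the
C0 control, plus the confirmatory C1-vs-C2 and C2-vs-C3 pairs), the Venn
partition and the regulatory-class calls, returning an
:class:`HsfMirnaResults` carrying the estimates and diagnostics.

Example
-------
>>> from stressmir import simulate, HsfMirnaModel
>>> cfg = simulate.DesignConfig(n_mirna=300, seed=7)
>>> truth = simulate.generate_truth(cfg)
>>> cm = simulate.simulate_counts(truth, cfg)
>>> res = HsfMirnaModel.from_count_matrix(cm).fit(test="nb_wald")
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as _classify
from . import diffexpr as _diffexpr
from . import enrich as _enrich
from . import networks as _networks
from .data import CountMatrix

_CONTRAST_PLAN = {
    # label -> (condition_a, condition_b); orientation is b vs a
    "C1_vs_C0": ("C0", "C1"),
    "C2_vs_C0": ("C0", "C2"),
    "C3_vs_C0": ("C0", "C3"),
    "C1_vs_C2": ("C2", "C1"),
    "C2_vs_C3": ("C3", "C2"),
}


class HsfMirnaModel:
    """miRNA regulatory-classification model for the 2x2 factorial design.

    Parameters
    ----------
    counts
        miRNA x sample count DataFrame.
    samples
        Sample sheet DataFrame (index sample id; columns ``condition`` in
        {C0..C3 or full labels} and ``replicate``).
    detection_filter
        ``"all_samples"`` (default, strict: reads in every replicate) or
        ``"any_condition"``.
    """

    def __init__(self, counts, samples, detection_filter: str = "all_samples"):
        self.data = CountMatrix(pd.DataFrame(counts), pd.DataFrame(samples))
        self.detection_filter = detection_filter

    @classmethod
    def from_count_matrix(cls, cm: CountMatrix, **kwargs) -> "HsfMirnaModel":
        return cls(cm.counts, cm.samples, **kwargs)

    @classmethod
    def from_tsv(cls, counts_path, samples_path, **kwargs) -> "HsfMirnaModel":
        cm = CountMatrix.from_tsv(counts_path, samples_path)
        return cls.from_count_matrix(cm, **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        test: str = "exact",
        normalization: str = "median_ratio",
        dispersion: float | None = None,
        pseudocount: float = 0.0,
    ) -> "HsfMirnaResults":
        """Run the full classification and return the results object.

        ``test`` selects the per-contrast statistic: ``"exact"`` (pooled
        conditional binomial; exact for Poisson replicates) or ``"nb_wald"``
        (common-dispersion negative-binomial Wald test; use for counts with
        biological overdispersion).  ``normalization`` selects the depth
        factors: ``"median_ratio"`` (default; robust to a minority of
        strongly regulated miRNAs skewing library totals) or ``"total"``.
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        filtered = _diffexpr.filter_detected(self.data, mode=self.detection_filter)
        if len(filtered.counts) == 0:
            raise ValueError("no miRNAs pass the detection filter")
        factors = _diffexpr.compute_size_factors(filtered, normalization)
        if test == "nb_wald" and dispersion is None:
            dispersion = _diffexpr.estimate_dispersion(filtered, factors)
        contrasts = {
            label: _diffexpr.contrast(
                filtered,
                a,
                b,
                method=test,
                dispersion=dispersion,
                factors=factors,
                pseudocount=pseudocount,
            )
            for label, (a, b) in _CONTRAST_PLAN.items()
        }
        control = {k: contrasts[k] for k in ("C1_vs_C0", "C2_vs_C0", "C3_vs_C0")}
        pairwise = {k: contrasts[k] for k in ("C1_vs_C2", "C2_vs_C3")}
        partition = _classify.venn_partition(control, alpha=alpha)
        calls = _classify.call_classes(control, pairwise, alpha=alpha)
        res = HsfMirnaResults(
            model=self,
            filtered=filtered,
            size_factors_=factors,
            contrasts=contrasts,
            partition=partition,
            calls=calls,
            alpha=alpha,
            test=test,
            dispersion=dispersion,
        )
        res.normalization = normalization
        return res


class HsfMirnaResults:
    """Fitted classification results.

    Attributes
    ----------
    contrasts : dict[str, ContrastResult]
        The five fitted contrasts keyed by label (e.g. ``"C1_vs_C0"``).
    calls : DataFrame
        Per-miRNA class calls with provenance (q-values, fold changes).
    partition : VennPartition
        Seven-region overlap structure of the control-relative contrasts.
    """

    def __init__(
        self,
        model,
        filtered,
        size_factors_,
        contrasts,
        partition,
        calls,
        alpha,
        test,
        dispersion,
    ):
        self.model = model
        self.filtered = filtered
        self.size_factors_ = size_factors_
        self.contrasts = contrasts
        self.partition = partition
        self.calls = calls
        self.alpha = alpha
        self.test = test
        self.dispersion = dispersion

    # -- reporting ---------------------------------------------------------

    def class_counts(self) -> pd.Series:
        order = ["hs_dep_up", "hs_dep_down", "hs_indep_up", "hs_indep_down", "unclassified"]
        vc = self.calls["class"].value_counts()
        return vc.reindex(order, fill_value=0)

    def class_table(self, cls: str) -> pd.DataFrame:
        """Members of one class with reported (sign-convention) fold changes."""
        sub = self.calls[self.calls["class"] == cls]
        return sub[["reported_log2fc"]].sort_values("reported_log2fc", ascending=False)

    def report(self) -> dict[str, pd.DataFrame]:
        return _classify.classification_report(self.calls, self.partition)

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        n_total = len(self.model.data.counts)
        n_kept = len(self.filtered.counts)
        cc = self.class_counts()
        lines = [
            "          HSF-1 miRNA Regulatory Classification",
            "=" * 58,
            f"miRNAs (input / detected):       {n_total} / {n_kept}",
            f"Test:                            {self.test}"
            + (
                f" (common dispersion {self.dispersion:.4g})"
                if self.dispersion is not None
                else ""
            ),
            f"Significance threshold:          q < {self.alpha} (BH per contrast)",
            "-" * 58,
            "Class                            n",
        ]
        for cls, n in cc.items():
            lines.append(f"  {cls:<30} {n}")
        lines.append("-" * 58)
        n_cand = int(self.calls["candidate"].sum())
        n_dual = int(self.calls["dual"].sum())
        lines.append(f"Candidates (Venn stage only):    {n_cand}")
        lines.append(f"Dual-eligible (dependent label): {n_dual}")
        for cls in ("hs_dep_up", "hs_dep_down", "hs_indep_up", "hs_indep_down"):
            tab = self.class_table(cls)
            if len(tab):
                members = ", ".join(
                    f"{m} ({v:+.2f})"
                    for m, v in tab["reported_log2fc"].head(5).items()
                )
                lines.append(f"{cls}: {members}" + (" ..." if len(tab) > 5 else ""))
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- QC / plots --------------------------------------------------------

    def replicate_qc(self) -> dict:
        return _diffexpr.replicate_qc(self.filtered)

    def volcano(self, label: str = "C1_vs_C0") -> pd.DataFrame:
        return _diffexpr.volcano_table(self.contrasts[label], alpha=self.alpha)

    def plot_volcano(self, label: str = "C1_vs_C0", ax=None):
        """Volcano plot for one contrast (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        tab = self.volcano(label)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        sig = tab["significant"]
        ax.scatter(tab.loc[~sig, "log2fc"], tab.loc[~sig, "neg_log10_q"], s=6, c="grey")
        ax.scatter(tab.loc[sig, "log2fc"], tab.loc[sig, "neg_log10_q"], s=8, c="crimson")
        ax.axhline(-np.log10(self.alpha), ls="--", lw=0.8, c="k")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 q")
        ax.set_title(label.replace("_", " "))
        return ax

    # -- downstream stages -------------------------------------------------

    def integrate(
        self,
        predictions: pd.DataFrame,
        regulation: pd.DataFrame,
        contrast: str,
        interactions: pd.DataFrame | None = None,
    ):
        """Inverse-correlation target filtering (and optional expansion).

        Returns the kept-edge table; with ``interactions`` supplied, returns
        ``(kept_edges, network, linkers)`` where the network embeds the kept
        target genes and their shared neighbors.
        """
        kept = _networks.integrate(self.calls, predictions, regulation, contrast)
        if interactions is None:
            return kept
        affected = {
            row.gene: ("up" if row.gene_log2fc > 0 else "down")
            for row in kept.itertuples(index=False)
        }
        network = _networks.expand_network(affected, interactions)
        linkers = _networks.find_linkers(network)
        return kept, network, linkers

    def enrich(
        self, genes, annotations: pd.DataFrame, universe=None, alpha: float | None = None
    ):
        """Term over-representation plus clustered enrichment scores."""
        alpha = self.alpha if alpha is None else alpha
        results = _enrich.enrich_terms(genes, annotations, universe, alpha=alpha)
        clusters = _enrich.cluster_terms(results)
        return results, clusters
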