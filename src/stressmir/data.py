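"""Core data containers shared across the pipeline.

The experimental design is a 2x2 factorial: *hsf-1* RNAi knockdown (+/-)
crossed with a 30-minute heat shock (+/-HS), each condition sequenced in
biological replicates.  Conditions carry both descriptive labels and the
short aliases C0..C3 used throughout:

    C0  hsf1_plus_noHS   empty-vector RNAi, no heat shock (the control)
    C1  hsf1_plus_HS     empty-vector RNAi, heat shock
    C2  hsf1_minus_HS    hsf-1 RNAi, heat shock
    C3  hsf1_minus_noHS  hsf-1 RNAi, no heat shock
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = (
    "hsf1_plus_noHS",
    "hsf1_plus_HS",
    "hsf1_minus_HS",
    "hsf1_minus_noHS",
)

CONDITION_ALIASES: dict[str, str] = {
    "C0": "hsf1_plus_noHS",
    "C1": "hsf1_plus_HS",
    "C2": "hsf1_minus_HS",
    "C3": "hsf1_minus_noHS",
}

#: Regulatory classes a miRNA can be assigned to.  "up"/"down" describe the
#: direction of HSF-1's normal regulatory effect on the miRNA.
CLASSES: tuple[str, ...] = (
    "hs_dep_up",
    "hs_dep_down",
    "hs_indep_up",
    "hs_indep_down",
    "unclassified",
)


def resolve_condition(label: str) -> str:
    """Map a condition alias (``C0``..``C3``) or full label to the full label."""
    if label in CONDITION_ALIASES:
        return CONDITION_ALIASES[label]
    if label in CONDITIONS:
        return label
    raise ValueError(
        f"unknown condition {label!r}; expected one of "
        f"{sorted(CONDITION_ALIASES)} or {list(CONDITIONS)}"
    )


@dataclass
class CountMatrix:
    """A miRNA x sample count table plus its sample sheet.

    Parameters
    ----------
    counts
        DataFrame indexed by miRNA id with one column per sample id.
        Counts must be nonnegative (fractional counts are allowed: the
        quantifier assigns multimapping reads fractionally).
    samples
        DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``.  Conditions may use C0..C3 aliases; they are
        normalized to the full labels on construction.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.samples = self.samples.copy()
        if "condition" not in self.samples.columns:
            raise ValueError("sample sheet must have a 'condition' column")
        if "replicate" not in self.samples.columns:
            raise ValueError("sample sheet must have a 'replicate' column")
        self.samples["condition"] = self.samples["condition"].map(resolve_condition)
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        if (np.asarray(self.counts, dtype=float) < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.samples["condition"]), key=CONDITIONS.index)

    def condition_samples(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in replicate order."""
        condition = resolve_condition(condition)
        sub = self.samples[self.samples["condition"] == condition]
        sub = sub.sort_values("replicate")
        missing = [s for s in sub.index if s not in self.counts.columns]
        if missing:
            raise ValueError(f"sample sheet entries without count columns: {missing}")
        return list(sub.index)

    def subset(self, mirnas) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(mirnas)], self.samples)

    # -- TSV round trip ----------------------------------------------------

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.rename_axis("mirna").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(counts, samples)


@dataclass
class ContrastResult:
    """Per-miRNA statistics for one oriented condition comparison (b vs a).

    ``table`` has columns ``mean_a``, ``mean_b`` (mean normalized counts),
    ``log2fc`` (log2(mean_b / mean_a)), ``pvalue`` and ``qvalue``
    (Benjamini-Hochberg adjusted within this contrast).
    """

    condition_a: str
    condition_b: str
    table: pd.DataFrame
    method: str = "exact"
    extra: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.condition_b}_vs_{self.condition_a}"

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]

    @property
    def mirnas(self) -> pd.Index:
        return self.table.index
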