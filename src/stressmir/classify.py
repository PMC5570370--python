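"""Regulatory-class calling for the 2x2 knockdown x heat-shock design.

Class semantics (directions describe HSF-1's normal regulatory effect):

* ``hs_dep_up`` / ``hs_dep_down`` — heat-shock-dependent regulation: the
  miRNA is significantly up/down in C1 vs C0 (heat shock with HSF-1
  present) AND significantly different between C1 and C2 (the effect needs
  HSF-1: it differs between hsf-1(+);+HS and hsf-1(-);+HS).
* ``hs_indep_up`` / ``hs_indep_down`` — heat-shock-independent regulation:
  the miRNA responds to hsf-1 knockdown alone (significant in C3 vs C0)
  with NO significant difference between the two knockdown conditions
  (C2 vs C3), i.e. heat shock is irrelevant once HSF-1 is gone.  The
  direction is reversed relative to the knockdown contrast: a miRNA that
  drops when hsf-1 is knocked down is normally UPregulated by HSF-1.  The
  reported fold change is correspondingly the negated C3-vs-C0 log2FC.

A miRNA eligible for both is labeled with the dependent class (precedence),
with both memberships preserved in the provenance columns.  A miRNA passing
a Venn (control-contrast) stage but failing its confirmatory pairwise test
is flagged as a candidate and left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ContrastResult

_REGIONS = ("100", "010", "001", "110", "101", "011", "111")


@dataclass
class VennPartition:
    """Disjoint overlap regions of the three control-relative significant sets.

    For each direction ("up", "down"), ``regions`` maps a membership key over
    (C1_vs_C0, C2_vs_C0, C3_vs_C0) — e.g. ``"101"`` = significant in the
    first and third contrasts only — to the sorted member list.
    """

    regions: dict[str, dict[str, list[str]]]
    alpha: float

    def counts(self) -> pd.DataFrame:
        rows = [
            (direction, key, len(members))
            for direction, regs in self.regions.items()
            for key, members in regs.items()
        ]
        return pd.DataFrame(rows, columns=["direction", "region", "count"])

    def union_size(self, direction: str) -> int:
        return sum(len(m) for m in self.regions[direction].values())


def _significant(res: ContrastResult, alpha: float, direction: str) -> set[str]:
    q = res["qvalue"]
    lfc = res["log2fc"]
    if direction == "up":
        mask = (q < alpha) & (lfc > 0)
    else:
        mask = (q < alpha) & (lfc < 0)
    return set(res.mirnas[mask])


def venn_partition(
    control_contrasts: dict[str, ContrastResult], alpha: float = 0.05
) -> VennPartition:
    """Seven-region Venn partition of the three control-relative contrasts.

    ``control_contrasts`` must contain keys ``C1_vs_C0``, ``C2_vs_C0`` and
    ``C3_vs_C0``; all three must share the same miRNA universe.  Membership
    is strict q < alpha, split by fold-change sign.
    """
    keys = ("C1_vs_C0", "C2_vs_C0", "C3_vs_C0")
    missing = [k for k in keys if k not in control_contrasts]
    if missing:
        raise ValueError(f"missing control contrasts: {missing}")
    universes = [set(control_contrasts[k].mirnas) for k in keys]
    if not (universes[0] == universes[1] == universes[2]):
        raise ValueError("control contrasts must share the same miRNA universe")
    out: dict[str, dict[str, list[str]]] = {}
    for direction in ("up", "down"):
        sets = [_significant(control_contrasts[k], alpha, direction) for k in keys]
        regions: dict[str, list[str]] = {}
        for key in _REGIONS:
            members = set.union(set(), *[s for s, b in zip(sets, key) if b == "1"])
            for s, b in zip(sets, key):
                members &= s if b == "1" else (universes[0] - s)
            regions[key] = sorted(members)
        out[direction] = regions
    return VennPartition(regions=out, alpha=alpha)


def call_classes(
    control_contrasts: dict[str, ContrastResult],
    pairwise_contrasts: dict[str, ContrastResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign each miRNA one regulatory class, with provenance.

    ``control_contrasts`` needs ``C1_vs_C0`` and ``C3_vs_C0`` (``C2_vs_C0``
    is carried for provenance when present); ``pairwise_contrasts`` needs
    ``C1_vs_C2`` and ``C2_vs_C3``.  Returns a DataFrame indexed by miRNA
    with columns: class, candidate, reported_log2fc, dep_eligible,
    indep_eligible, dual, and the driving q-values / fold changes.
    """
    for key in ("C1_vs_C0", "C3_vs_C0"):
        if key not in control_contrasts:
            raise ValueError(f"missing control contrast {key}")
    for key in ("C1_vs_C2", "C2_vs_C3"):
        if key not in pairwise_contrasts:
            raise ValueError(f"missing pairwise contrast {key}")

    c1 = control_contrasts["C1_vs_C0"].table
    c3 = control_contrasts["C3_vs_C0"].table
    p12 = pairwise_contrasts["C1_vs_C2"].table
    p23 = pairwise_contrasts["C2_vs_C3"].table
    universe = c1.index
    for other in (c3, p12, p23):
        if not universe.equals(other.index):
            if set(universe) != set(other.index):
                raise ValueError("contrasts must share the same miRNA universe")

    q1 = c1["qvalue"].reindex(universe).to_numpy()
    lfc1 = c1["log2fc"].reindex(universe).to_numpy()
    q3 = c3["qvalue"].reindex(universe).to_numpy()
    lfc3 = c3["log2fc"].reindex(universe).to_numpy()
    q12 = p12["qvalue"].reindex(universe).to_numpy()
    q23 = p23["qvalue"].reindex(universe).to_numpy()

    dep_sig = q1 < alpha
    dep_confirmed = dep_sig & (q12 < alpha)
    indep_sig = q3 < alpha
    indep_confirmed = indep_sig & (q23 >= alpha)

    cls = np.full(len(universe), "unclassified", dtype=object)
    reported = np.full(len(universe), np.nan)
    # independent calls first; dependent calls then take precedence
    up_by_hsf1 = indep_confirmed & (lfc3 < 0)  # drops on knockdown
    down_by_hsf1 = indep_confirmed & (lfc3 > 0)  # rises on knockdown
    cls[up_by_hsf1] = "hs_indep_up"
    cls[down_by_hsf1] = "hs_indep_down"
    reported[indep_confirmed] = -lfc3[indep_confirmed]
    cls[dep_confirmed & (lfc1 > 0)] = "hs_dep_up"
    cls[dep_confirmed & (lfc1 < 0)] = "hs_dep_down"
    reported[dep_confirmed & (lfc1 != 0)] = lfc1[dep_confirmed & (lfc1 != 0)]

    candidate = ((dep_sig & ~dep_confirmed) | (indep_sig & ~indep_confirmed)) & (
        cls == "unclassified"
    )
    calls = pd.DataFrame(
        {
            "class": cls,
            "candidate": candidate,
            "reported_log2fc": reported,
            "dep_eligible": dep_confirmed,
            "indep_eligible": indep_confirmed,
            "dual": dep_confirmed & indep_confirmed,
            "log2fc_C1_vs_C0": lfc1,
            "q_C1_vs_C0": q1,
            "log2fc_C3_vs_C0": lfc3,
            "q_C3_vs_C0": q3,
            "q_C1_vs_C2": q12,
            "q_C2_vs_C3": q23,
        },
        index=universe.rename("mirna"),
    )
    return calls


def classification_report(
    calls: pd.DataFrame, partition: VennPartition | None = None
) -> dict[str, pd.DataFrame]:
    """Per-class member tables (with reported fold changes) and Venn counts."""
    tables: dict[str, pd.DataFrame] = {}
    for cls in ("hs_dep_up", "hs_dep_down", "hs_indep_up", "hs_indep_down"):
        sub = calls[calls["class"] == cls]
        tables[cls] = sub[["reported_log2fc"]].sort_values(
            "reported_log2fc", ascending=False
        )
    tables["class_counts"] = (
        calls["class"].value_counts().rename_axis("class").to_frame("count")
    )
    if partition is not None:
        tables["venn_regions"] = partition.counts()
    return tables
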