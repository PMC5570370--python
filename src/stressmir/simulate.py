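"""Synthetic data with planted ground truth for the 2x2 knockdown x heat-shock design.

Every input the pipeline consumes can be generated here with known truth:
negative-binomial replicate counts with planted regulatory classes,
adapter-bearing small-RNA reads, miRNA->gene target maps with a controlled
fraction of inversely regulated targets, gene-gene interaction edges, and
annotation tables with planted enriched terms.

The count model is a negative binomial with a single shared dispersion
``alpha`` (variance mu + alpha * mu^2); ``alpha = 0`` degenerates to
Poisson.  Per-sample sequencing-depth variation is a lognormal
multiplicative library-size factor.  Planted classes modulate condition
means by a factor of ``2**effect_log2fc``:

    hs_dep_up     induced by HSF-1 only under heat shock: mean x 2^e in C1
    hs_dep_down   repressed by HSF-1 only under heat shock: mean / 2^e in C1
    hs_indep_up   maintained by HSF-1 regardless of heat shock:
                  mean / 2^e in both knockdown conditions (C2, C3)
    hs_indep_down suppressed by HSF-1 regardless of heat shock:
                  mean x 2^e in both knockdown conditions (C2, C3)
    unclassified  equal means everywhere
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CLASSES, CONDITIONS, CountMatrix

#: Standard Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_DEFAULT_FRACTIONS = {
    "hs_dep_up": 0.05,
    "hs_dep_down": 0.05,
    "hs_indep_up": 0.05,
    "hs_indep_down": 0.05,
    "unclassified": 0.80,
}


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the simulated 2x2 design.

    Defaults mirror the study conditions used for recovery testing: 1,000
    miRNAs, biological duplicates, baseline mean 500 reads, negative-binomial
    dispersion 0.05, planted |log2FC| of 3, 20% of miRNAs regulated (split
    evenly over the four classes), mild lognormal depth jitter.
    """

    n_mirna: int = 1000
    n_replicates: int = 2
    baseline_mean: float = 500.0
    dispersion: float = 0.05
    class_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    effect_log2fc: float = 3.0
    library_size_spread: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna <= 0:
            raise ValueError("n_mirna must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.library_size_spread < 0:
            raise ValueError("library_size_spread must be nonnegative")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_fractions: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class_fractions must sum to 1, got {total!r}")

    def fraction_vector(self) -> np.ndarray:
        return np.array([self.class_fractions.get(c, 0.0) for c in CLASSES])


@dataclass
class SynthTruth:
    """Planted ground truth: per-miRNA class and per-condition expected mean.

    ``means`` is a DataFrame (miRNA x condition) of expected counts before
    library-size scaling.  Target-map and annotation truth is attached by
    the corresponding generators.
    """

    classes: pd.Series
    means: pd.DataFrame
    target_edges: pd.DataFrame | None = None
    planted_terms: list[str] = field(default_factory=list)

    @property
    def mirnas(self) -> pd.Index:
        return self.classes.index

    def class_members(self, cls: str) -> list[str]:
        return list(self.classes.index[self.classes == cls])


def _class_multipliers(cls: str, effect: float) -> np.ndarray:
    """Per-condition (C0..C3) mean multipliers for one regulatory class."""
    up = 2.0**effect
    m = np.ones(4)
    if cls == "hs_dep_up":
        m[1] = up
    elif cls == "hs_dep_down":
        m[1] = 1.0 / up
    elif cls == "hs_indep_up":
        m[2] = m[3] = 1.0 / up
    elif cls == "hs_indep_down":
        m[2] = m[3] = up
    elif cls != "unclassified":
        raise ValueError(f"unknown class {cls!r}")
    return m


def generate_truth(config: DesignConfig) -> SynthTruth:
    """Assign each miRNA a regulatory class and expected per-condition means.

    Classes are drawn i.i.d. from ``class_fractions``; expected means are the
    shared baseline modulated by the class multipliers.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ids = pd.Index(
        [f"syn-mir-{i + 1}-5p" for i in range(config.n_mirna)], name="mirna"
    )
    labels = rng.choice(len(CLASSES), size=config.n_mirna, p=config.fraction_vector())
    classes = pd.Series([CLASSES[k] for k in labels], index=ids, name="class")
    mult = np.stack(
        [_class_multipliers(c, config.effect_log2fc) for c in classes], axis=0
    )
    means = pd.DataFrame(
        config.baseline_mean * mult, index=ids, columns=list(CONDITIONS)
    )
    return SynthTruth(classes=classes, means=means)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion  # NB shape parameter; variance = mu + alpha mu^2
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(truth: SynthTruth, config: DesignConfig) -> CountMatrix:
    """Draw replicate counts for every miRNA and sample.

    Counts are negative binomial with the truth mean scaled by a per-sample
    lognormal library-size factor (sigma = ``library_size_spread``).
    Reproducible given ``config.seed``.
    """
    if len(truth.mirnas) != config.n_mirna:
        raise ValueError("truth and config disagree on n_mirna")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sample_ids, conditions, replicates = [], [], []
    for cond in CONDITIONS:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{cond}_r{r}")
            conditions.append(cond)
            replicates.append(r)
    factors = np.exp(
        rng.normal(0.0, config.library_size_spread, size=len(sample_ids))
    )
    columns = {}
    for sample, cond, factor in zip(sample_ids, conditions, factors):
        mu = truth.means[cond].to_numpy() * factor
        columns[sample] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(columns, index=truth.mirnas)
    samples = pd.DataFrame(
        {"condition": conditions, "replicate": replicates},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(counts, samples)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reference(
    mirnas, length: int = 22, seed: int = 0, min_distance: int = 8
) -> dict[str, str]:
    """Random mature sequences, mutually distant so mapping is unambiguous.

    Rejection-samples until every pair differs at >= ``min_distance``
    positions (trivially satisfied for random sequences at realistic sizes).
    """
    rng = np.random.default_rng(seed)
    seqs: list[np.ndarray] = []
    for _ in mirnas:
        while True:
            cand = rng.integers(0, 4, size=length)
            if all((cand != s).sum() >= min_distance for s in seqs):
                seqs.append(cand)
                break
    return {
        m: "".join("ACGT"[b] for b in s) for m, s in zip(mirnas, seqs)
    }


def simulate_reads(
    counts: CountMatrix,
    reference: dict[str, str],
    adapter: str = DEFAULT_ADAPTER,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Emit per-sample reads: mature sequence (with substitution errors) + adapter.

    Returns ``{sample_id: [(read_id, sequence), ...]}``; exactly ``count``
    reads per miRNA per sample (counts are rounded to integers).  Per-base
    substitution errors occur independently at ``error_rate`` within the
    mature portion only.
    """
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    missing = set(counts.counts.index) - set(reference)
    if missing:
        raise ValueError(f"no reference sequence for: {sorted(missing)[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out: dict[str, list[tuple[str, str]]] = {}
    for sample in counts.counts.columns:
        reads: list[tuple[str, str]] = []
        for mirna, n in counts.counts[sample].items():
            n = int(round(n))
            if n <= 0:
                continue
            mature = np.frombuffer(reference[mirna].encode(), dtype=np.uint8)
            for i in range(n):
                seq = mature.copy()
                if error_rate > 0:
                    hit = rng.random(len(seq)) < error_rate
                    if hit.any():
                        # substitute with one of the three other bases
                        shift = rng.integers(1, 4, size=int(hit.sum()))
                        idx = np.searchsorted(_BASES, seq[hit])
                        seq[hit] = _BASES[(idx + shift) % 4]
                reads.append(
                    (f"{sample}:{mirna}:{i}", seq.tobytes().decode() + adapter)
                )
        out[sample] = reads
    return out


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as 4-line FASTQ with placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(reference: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reference.items():
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Target maps, annotations, interactions
# ---------------------------------------------------------------------------


def _mirna_direction(cls: str) -> int:
    """+1 if HSF-1 normally upregulates the miRNA, -1 if it downregulates."""
    if cls in ("hs_dep_up", "hs_indep_up"):
        return 1
    if cls in ("hs_dep_down", "hs_indep_down"):
        return -1
    return 0


def simulate_target_map(
    truth: SynthTruth,
    n_genes: int,
    frac_inverse: float,
    targets_per_mirna: int = 20,
    contrast_label: str = "hsf1_regulation",
    effect_log2fc: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predicted targets plus an mRNA regulation table with planted truth.

    Each classified miRNA receives ``targets_per_mirna`` predicted targets,
    each a distinct gene (so the planted keepable set is unambiguous).  A
    fraction ``frac_inverse`` of edges point at genes whose planted mRNA
    log2FC is significant and OPPOSITE in sign to the miRNA's regulatory
    direction (these are the keepable edges); the rest are split between
    significant same-sign and non-significant targets.  Untargeted genes get
    background (non-significant) regulation rows.  Attaches
    ``truth.target_edges`` with a boolean ``keepable`` column.
    """
    if not 0 <= frac_inverse <= 1:
        raise ValueError("frac_inverse must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    regulated = [m for m in truth.mirnas if truth.classes[m] != "unclassified"]
    n_edges = len(regulated) * targets_per_mirna
    if n_genes < n_edges:
        raise ValueError(
            f"n_genes={n_genes} too small for {n_edges} unique target edges"
        )
    genes = [f"gene-{i + 1:05d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)

    pred_rows, reg_sign, reg_sig, edge_rows = [], {}, {}, []
    k = 0
    for mirna in regulated:
        direction = _mirna_direction(truth.classes[mirna])
        for _ in range(targets_per_mirna):
            gene = genes[perm[k]]
            k += 1
            keep = rng.random() < frac_inverse
            if keep:
                sign, sig = -direction, True
            elif rng.random() < 0.5:
                sign, sig = direction, True  # same-sign: fails the inverse rule
            else:
                sign, sig = (-direction if rng.random() < 0.5 else direction), False
            reg_sign[gene] = sign
            reg_sig[gene] = sig
            pred_rows.append((mirna, gene, float(rng.uniform(0.5, 1.0)), "primary_predictor"))
            edge_rows.append((mirna, gene, keep))

    reg_rows = []
    for gene in genes:
        if gene in reg_sign:
            lfc = reg_sign[gene] * (effect_log2fc + rng.exponential(0.3))
            sig = reg_sig[gene]
        else:
            lfc = rng.normal(0.0, 0.2)
            sig = False
        reg_rows.append((gene, contrast_label, float(lfc), bool(sig)))

    predictions = pd.DataFrame(
        pred_rows, columns=["mirna", "gene", "score", "source"]
    )
    regulation = pd.DataFrame(
        reg_rows, columns=["gene", "contrast", "log2fc", "significant"]
    )
    truth.target_edges = pd.DataFrame(
        edge_rows, columns=["mirna", "gene", "keepable"]
    )
    return predictions, regulation


def simulate_annotations(
    genes,
    target_genes,
    n_terms: int = 50,
    term_size: int = 20,
    enrichment_factor: float = 10.0,
    n_planted: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Term->gene annotation table with ``n_planted`` terms enriched for targets.

    Planted terms sample genes with weight ``enrichment_factor`` on the
    target-gene set (weight 1 elsewhere); background terms sample uniformly.
    ``enrichment_factor = 1`` is the null.  Returns the table and the planted
    term ids.
    """
    genes = list(genes)
    if term_size > len(genes):
        raise ValueError("term size exceeds gene universe")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    target_set = set(target_genes)
    weights = np.array(
        [enrichment_factor if g in target_set else 1.0 for g in genes]
    )
    weights = weights / weights.sum()
    rows, planted = [], []
    for t in range(n_terms):
        term = f"TERM:{t + 1:04d}"
        if t < n_planted:
            members = rng.choice(genes, size=term_size, replace=False, p=weights)
            planted.append(term)
        else:
            members = rng.choice(genes, size=term_size, replace=False)
        for g in members:
            rows.append((term, f"process {t + 1}", g))
    table = pd.DataFrame(rows, columns=["term_id", "term_name", "gene"])
    return table, planted


def simulate_interactions(
    genes, edge_density: float = 0.01, seed: int = 0
) -> pd.DataFrame:
    """Undirected gene-gene edges drawn uniformly at the given density.

    Samples Binomial(n_pairs, density) distinct unordered pairs without
    materialising the full pair list, so it scales to large gene universes.
    """
    genes = list(genes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    n = len(genes)
    rows: list[tuple[str, str]] = []
    n_pairs = n * (n - 1) // 2
    if n_pairs > 0 and edge_density > 0:
        n_edges = rng.binomial(n_pairs, edge_density)
        # unordered pair <-> linear index in the upper triangle
        chosen = rng.choice(n_pairs, size=n_edges, replace=False)
        chosen.sort()
        # invert k = C(i) + (j - i - 1) with C(i) = i*(2n - i - 1)/2
        def cum(i: int) -> int:
            return i * (2 * n - i - 1) // 2

        for k in chosen:
            k = int(k)
            i = int((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * k)) // 2)
            while cum(i + 1) <= k:
                i += 1
            while cum(i) > k:
                i -= 1
            j = k - cum(i) + i + 1
            rows.append((genes[i], genes[j]))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"])
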