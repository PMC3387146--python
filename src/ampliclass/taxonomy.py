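"""Word-based naive-Bayes taxonomic classification with bootstrap confidence.

Each reference sequence carries a ranked lineage (domain ... genus).  Training
records, for every 8-mer word w, the number of reference sequences containing
w overall (``n(w)`` of ``N``) and within each genus (``m(w, g)`` of ``M(g)``).
The word prior and genus-conditional probabilities use the classic
pseudocounts

    P(w)   = (n(w) + 0.5) / (N + 1)
    P(w|g) = (m(w, g) + P(w)) / (M(g) + 1)

A query read is scored per genus by summing ``log P(w|g)`` over its distinct
words; the highest-scoring genus wins (ties broken toward the
lexicographically smallest genus, with a tie flag).  Confidence at each rank
is estimated by bootstrap: ``n_bootstrap`` draws of ``ceil(V/8)`` words with
replacement (V = number of distinct words in the read), each re-scored; the
confidence of a rank label is the fraction of draws whose winning genus maps
to that label.  Ranks below the first rank whose confidence falls under the
threshold are reported unclassified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class ReferenceDB:
    """Training sequences with complete ranked lineages.

    ``records`` holds ``(id, sequence, lineage)`` triples where ``lineage`` is
    a tuple of labels, one per rank in ``ranks`` (coarsest first, genus last).
    """

    records: list[tuple[str, str, tuple[str, ...]]]
    ranks: tuple[str, ...] = DEFAULT_RANKS

    def __post_init__(self) -> None:
        for rid, seq, lineage in self.records:
            if len(lineage) != len(self.ranks):
                raise ValueError(
                    f"record {rid}: lineage has {len(lineage)} labels, "
                    f"expected {len(self.ranks)} ({'/'.join(self.ranks)})")

    @property
    def genera(self) -> list[str]:
        return sorted({lin[-1] for _, _, lin in self.records})

    @classmethod
    def from_fasta(cls, path: str | Path, ranks: Sequence[str] = DEFAULT_RANKS) -> "ReferenceDB":
        """Parse a reference FASTA whose headers are ``>id Domain;...;Genus``."""
        from Bio import SeqIO

        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            lineage = tuple(x.strip() for x in rec.description.split(None, 1)[1].split(";"))
            records.append((rec.id, str(rec.seq).upper(), lineage))
        return cls(records, tuple(ranks))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq, lineage in self.records:
                fh.write(f">{rid} {';'.join(lineage)}\n{seq}\n")


@dataclass
class TaxonomyModel:
    """Fitted word statistics for naive-Bayes genus assignment."""

    word_size: int
    genera: list[str]                       # sorted; column order of log_cond
    word_index: dict[str, int]
    log_cond: np.ndarray                    # V x G matrix of log P(w|g)
    log_unseen: np.ndarray                  # length-G log P(w|g) for unseen w
    lineages: dict[str, tuple[str, ...]]    # genus -> full lineage
    ranks: tuple[str, ...] = DEFAULT_RANKS

    def word_matrix(self, words: Sequence[str]) -> np.ndarray:
        """Per-word log-likelihood rows (len(words) x G) for a query read."""
        rows = np.empty((len(words), len(self.genera)))
        for i, w in enumerate(words):
            j = self.word_index.get(w, -1)
            rows[i] = self.log_cond[j] if j >= 0 else self.log_unseen
        return rows


@dataclass
class LineageAssignment:
    """Per-rank label and bootstrap confidence for one read."""

    read_id: str
    labels: dict[str, str | None]          # rank -> label (None = unclassified)
    confidences: dict[str, float]
    best_genus: str | None
    tie: bool = False
    unclassified_reason: str | None = None
    sample: str | None = None


def distinct_words(seq: str, k: int) -> list[str]:
    """Distinct k-mers of a sequence, in order of first occurrence.

    Words containing ambiguous characters are skipped.
    """
    seen: dict[str, None] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if w not in seen and all(b in "ACGT" for b in w):
            seen[w] = None
    return list(seen)


def train(reference: ReferenceDB, word_size: int = 8) -> TaxonomyModel:
    """Fit word priors and genus-conditional word probabilities."""
    if not reference.records:
        raise ValueError("reference database is empty")
    seen_pairs: set[tuple[str, str]] = set()
    records = []
    for rid, seq, lineage in reference.records:
        key = (rid, seq)
        if key in seen_pairs:
            warnings.warn(f"duplicate reference record {rid!r} collapsed")
            continue
        seen_pairs.add(key)
        if len(seq) < word_size:
            raise ValueError(f"reference sequence {rid} shorter than word size")
        records.append((rid, seq, lineage))

    genera = sorted({lin[-1] for _, _, lin in records})
    gidx = {g: i for i, g in enumerate(genera)}
    lineages: dict[str, tuple[str, ...]] = {}
    for _, _, lin in records:
        prev = lineages.setdefault(lin[-1], lin)
        if prev != lin:
            raise ValueError(f"genus {lin[-1]} has conflicting lineages")

    N = len(records)
    M = np.zeros(len(genera))
    word_index: dict[str, int] = {}
    n_counts: list[int] = []
    m_counts: list[np.ndarray] = []
    for _, seq, lin in records:
        g = gidx[lin[-1]]
        M[g] += 1
        for w in distinct_words(seq, word_size):
            j = word_index.get(w)
            if j is None:
                j = word_index[w] = len(n_counts)
                n_counts.append(0)
                m_counts.append(np.zeros(len(genera)))
            n_counts[j] += 1
            m_counts[j][g] += 1

    n = np.asarray(n_counts, dtype=float)
    m = np.stack(m_counts) if m_counts else np.zeros((0, len(genera)))
    prior = (n + 0.5) / (N + 1)                       # P(w), in (0, 1)
    cond = (m + prior[:, None]) / (M[None, :] + 1.0)  # P(w|g)
    unseen_prior = 0.5 / (N + 1)
    return TaxonomyModel(
        word_size=word_size,
        genera=genera,
        word_index=word_index,
        log_cond=np.log(cond),
        log_unseen=np.log(unseen_prior / (M + 1.0)),
        lineages=lineages,
        ranks=reference.ranks,
    )


def _winning_genus(scores: np.ndarray, genera: list[str]) -> tuple[int, bool]:
    """Argmax with lowest-lexicographic tie-break (genera are sorted)."""
    best = int(np.argmax(scores))
    tie = int(np.sum(scores == scores[best])) > 1
    return best, tie


def classify(
    model: TaxonomyModel,
    read,
    n_bootstrap: int = 100,
    confidence_threshold: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> LineageAssignment:
    """Assign a ranked lineage with bootstrap confidence to one read.

    ``read`` may be an object with ``.id``/``.bases`` (e.g. AmpliconRead) or a
    bare ``(id, sequence)`` pair.
    """
    if hasattr(read, "bases"):
        rid, seq, sample = read.id, read.bases, getattr(read, "sample", None)
    else:
        rid, seq = read
        sample = None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ranks = model.ranks
    if len(seq) < model.word_size:
        return LineageAssignment(rid, {r: None for r in ranks},
                                 {r: 0.0 for r in ranks}, None,
                                 unclassified_reason="too_short", sample=sample)
    words = distinct_words(seq, model.word_size)
    if not words:
        return LineageAssignment(rid, {r: None for r in ranks},
                                 {r: 0.0 for r in ranks}, None,
                                 unclassified_reason="no_valid_words", sample=sample)

    W = model.word_matrix(words)                     # V x G
    best, tie = _winning_genus(W.sum(axis=0), model.genera)
    best_lineage = model.lineages[model.genera[best]]

    V = len(words)
    draw_size = int(np.ceil(V / 8))
    draws = rng.integers(0, V, size=(n_bootstrap, draw_size))
    boot_scores = W[draws].sum(axis=1)               # n_bootstrap x G
    winners = np.argmax(boot_scores, axis=1)

    # map bootstrap winners to labels at each rank and compare to best lineage
    lineage_matrix = np.array(
        [model.lineages[g] for g in model.genera], dtype=object)  # G x R
    labels: dict[str, str | None] = {}
    confs: dict[str, float] = {}
    cut = False
    for ri, rank in enumerate(ranks):
        conf = float(np.mean(lineage_matrix[winners, ri] == best_lineage[ri]))
        confs[rank] = conf
        if conf < confidence_threshold:
            cut = True
        labels[rank] = None if cut else best_lineage[ri]
    return LineageAssignment(rid, labels, confs, model.genera[best],
                             tie=tie, sample=sample)


def assign_all(
    model: TaxonomyModel,
    reads: Iterable,
    n_bootstrap: int = 100,
    confidence_threshold: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify a batch of reads; order-preserving, reproducible given seed.

    Returns one row per read with ``read_id``, ``sample``, ``best_genus``,
    ``tie``, ``unclassified_reason`` and per-rank label/confidence columns.
    Per-read random streams are derived from the master seed and the read's
    position, so batch order or subsetting does not change any single read's
    bootstrap draw.
    """
    rows = []
    for i, read in enumerate(reads):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        a = classify(model, read, n_bootstrap, confidence_threshold, rng)
        row = {"read_id": a.read_id, "sample": a.sample, "best_genus": a.best_genus,
               "tie": a.tie, "unclassified_reason": a.unclassified_reason}
        for rank in model.ranks:
            row[rank] = a.labels[rank]
            row[f"{rank}_confidence"] = a.confidences[rank]
        rows.append(row)
    cols = (["read_id", "sample", "best_genus", "tie", "unclassified_reason"]
            + [c for rank in model.ranks for c in (rank, f"{rank}_confidence")])
    table = pd.DataFrame(rows, columns=cols)
    for rank in model.ranks:
        n_unc = int(table[rank].isna().sum()) if len(table) else 0
        logger.info("rank %s: %d/%d reads classified", rank, len(table) - n_unc, len(table))
    return table


def write_assignments(table: pd.DataFrame, path: str | Path) -> None:
    """Write assignments as a long TSV (read_id, rank, label, confidence)."""
    ranks = [c for c in table.columns
             if f"{c}_confidence" in table.columns]
    long = table.melt(id_vars=["read_id"], value_vars=ranks,
                      var_name="rank", value_name="label")
    confs = table.melt(id_vars=["read_id"],
                       value_vars=[f"{r}_confidence" for r in ranks],
                       var_name="rank", value_name="confidence")
    long["confidence"] = confs["confidence"]
    long.to_csv(path, sep="\t", index=False)
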