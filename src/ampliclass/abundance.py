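"""Taxa-by-sample count tables, relative abundances and Shannon diversity.

Features are rank-qualified taxa (e.g. ``genus:Subdoligranulum``) so that
several taxonomic ranks can coexist in one table without name collisions.
Within each rank the features partition a sample's classified reads, so each
rank block's column sums equal the sample read count and normalizing a block
yields relative abundances that sum to one.  Reads unclassified at a rank are
binned under ``unclassified_<parent label>`` to preserve that partition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTable:
    """Taxa x sample counts with per-sample metadata.

    ``counts`` is features x samples (non-negative integers), ``metadata`` is
    samples x fields.  ``frequencies`` is filled by :func:`normalize`.
    ``ranks`` maps each feature to its taxonomic rank; when absent all
    features form a single block.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = None
    frequencies: pd.DataFrame | None = None
    ranks: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.counts.columns)
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dups}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")
        missing = self.counts.columns.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {list(missing)}")
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def rank_blocks(self) -> dict[str, pd.Index]:
        """Feature index per rank (single block ``'all'`` when ranks absent)."""
        if self.ranks is None:
            return {"all": self.counts.index}
        return {r: self.counts.index[self.ranks.loc[self.counts.index] == r]
                for r in self.ranks.loc[self.counts.index].unique()}

    def zero_depth_samples(self) -> list[str]:
        return list(self.counts.columns[self.counts.sum(axis=0) == 0])

    # -- persistence ------------------------------------------------------

    def to_tsv(self, counts_path: str | Path, metadata_path: str | Path | None = None) -> None:
        out = self.counts.copy()
        out.insert(0, "rank", self.ranks.loc[out.index] if self.ranks is not None else "all")
        out.to_csv(counts_path, sep="\t", index_label="feature")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample")

    def to_biom_json(self, path: str | Path) -> None:
        """Minimal BIOM-format (v1, dense) JSON export of the count table."""
        import datetime
        import json

        biom = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "ampliclass",
            "date": datetime.datetime.now().isoformat(),
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [len(self.features), len(self.samples)],
            "rows": [{"id": f, "metadata": None} for f in self.features],
            "columns": [{"id": s,
                         "metadata": self.metadata.loc[s].to_dict() or None}
                        for s in self.samples],
            "data": self.counts.to_numpy().tolist(),
        }
        Path(path).write_text(json.dumps(biom))

    @classmethod
    def from_tsv(cls, counts_path: str | Path,
                 metadata_path: str | Path | None = None) -> "AbundanceTable":
        raw = pd.read_csv(counts_path, sep="\t", index_col="feature")
        raw.index.name = None
        ranks = raw.pop("rank")
        ranks.name = None
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
            meta.index = meta.index.astype(str)
            meta.index.name = None
        counts = raw
        counts.columns = counts.columns.astype(str)
        return cls(counts=counts, metadata=meta,
                   ranks=None if (ranks == "all").all() else ranks)


def tabulate(assignments: pd.DataFrame, ranks: Sequence[str],
             samples: Sequence[str] | None = None,
             include_unclassified: bool = True) -> AbundanceTable:
    """Count classified reads per rank-qualified taxon per sample.

    ``assignments`` is the output of :func:`ampliclass.taxonomy.assign_all`
    and must carry a ``sample`` column.  For each requested rank, reads with
    no label at that rank are binned as ``unclassified_<parent>`` (the finest
    available coarser label) so each rank block partitions the sample's reads.
    Features with zero total count are dropped with a log line.
    """
    if "sample" not in assignments.columns or assignments["sample"].isna().any():
        raise ValueError("assignments must carry a sample id for every read")
    for rank in ranks:
        if rank not in assignments.columns:
            raise ValueError(f"rank {rank!r} not present in assignments")
    all_ranks = [c for c in assignments.columns if f"{c}_confidence" in assignments.columns]
    if samples is None:
        samples = list(pd.unique(assignments["sample"]))

    blocks, block_ranks = [], []
    for rank in ranks:
        labels = assignments[rank].copy()
        if include_unclassified:
            parent = pd.Series("root", index=assignments.index)
            for coarser in all_ranks[: all_ranks.index(rank)]:
                known = assignments[coarser].notna()
                parent[known] = assignments.loc[known, coarser]
            labels = labels.where(labels.notna(), "unclassified_" + parent.astype(str))
        else:
            labels = labels.dropna()
        counts = (
            pd.crosstab(labels, assignments.loc[labels.index, "sample"])
            .reindex(columns=samples, fill_value=0)
        )
        counts.index = [f"{rank}:{t}" for t in counts.index]
        blocks.append(counts)
        block_ranks.extend([rank] * len(counts))

    counts = pd.concat(blocks)
    counts.index.name = None
    counts.columns.name = None
    ranks_series = pd.Series(block_ranks, index=counts.index)
    empty = counts.index[counts.sum(axis=1) == 0]
    if len(empty):
        logger.info("dropping %d features with zero total count", len(empty))
        counts = counts.drop(index=empty)
        ranks_series = ranks_series.drop(index=empty)
    zero = counts.columns[counts.sum(axis=0) == 0]
    for s in zero:
        logger.warning("sample %s has zero classified reads", s)
    return AbundanceTable(counts=counts.astype(int), ranks=ranks_series)


def normalize(table: AbundanceTable) -> AbundanceTable:
    """Relative abundance: each count divided by its sample's rank-block total.

    Zero-depth samples keep zero frequencies and are reported by
    ``zero_depth_samples()``; downstream statistics exclude them unless
    forced.  Idempotent: normalizing an already normalized table recomputes
    the same frequencies from the unchanged counts.
    """
    freq = table.counts.astype(float).copy()
    for _, idx in table.rank_blocks().items():
        block = freq.loc[idx]
        totals = block.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq.loc[idx] = block.div(totals.where(totals > 0), axis=1).fillna(0.0)
    for s in table.zero_depth_samples():
        logger.warning("sample %s has zero depth; frequencies left at 0", s)
    return replace(table, frequencies=freq)


def shannon(counts, base: float = math.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive-count taxa.

    Natural log by default; ``base`` switches the logarithm.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero sample: Shannon diversity undefined")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / math.log(base))).sum())


def sample_diversity(table: AbundanceTable, rank: str | None = "genus",
                     base: float = math.e) -> pd.Series:
    """Per-sample Shannon diversity at one rank (genus by default)."""
    if table.ranks is None or rank is None:
        idx = table.counts.index
    else:
        idx = table.counts.index[table.ranks.loc[table.counts.index] == rank]
        if not len(idx):
            raise ValueError(f"no features at rank {rank!r}")
    block = table.counts.loc[idx]
    vals = {}
    for s in table.samples:
        col = block[s].to_numpy()
        vals[s] = shannon(col, base=base) if col.sum() > 0 else np.nan
    return pd.Series(vals, name="shannon")


def attach_diversity(table: AbundanceTable, rank: str | None = "genus") -> AbundanceTable:
    """Append per-sample Shannon diversity as one extra feature row."""
    div = sample_diversity(table, rank=rank)
    counts = table.counts.copy()
    ranks = table.ranks
    name = "diversity:shannon"
    freq = table.frequencies
    if freq is not None:
        freq = pd.concat([freq, div.rename(name).to_frame().T])
    counts = pd.concat([counts, div.rename(name).to_frame().T])
    if ranks is not None:
        ranks = pd.concat([ranks, pd.Series({name: "diversity"})])
    return replace(table, counts=counts, frequencies=freq, ranks=ranks)
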