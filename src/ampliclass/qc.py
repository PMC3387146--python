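"""Demultiplexing, quality filtering and trimming of multiplexed amplicon reads.

Raw 454-style amplicon reads arrive as a single multiplexed pool in which each
read begins with a sample barcode followed by the forward PCR primer, the 16S
template, and the reverse primer near the 3' end.  This module assigns reads to
samples by exact barcode match and applies the curation rules used for
MOTHUR-era amplicon surveys, in a fixed order:

1. length outside [min_len, max_len] nt          -> too_short / too_long
2. mean Phred quality below min_mean_quality     -> low_quality
3. ambiguous characters (non-ACGT)               -> ambiguous
4. more than ``max_reverse_primer_mismatches``
   against the reverse primer (IUPAC-aware)      -> primer_mismatch

Reads passing every rule have barcode and primers trimmed.  Chimera detection
itself is out of scope; :func:`apply_chimera_report` drops reads named by an
externally produced report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import PairedFastaQualIterator
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

REJECT_REASONS = (
    "too_short",
    "too_long",
    "low_quality",
    "ambiguous",
    "barcode_mismatch",
    "primer_mismatch",
    "chimeric",
)

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


class ConfigurationError(ValueError):
    """Raised for invalid QC policies (duplicate or nested barcodes, ...)."""


@dataclass
class AmpliconRead:
    """One amplicon sequence with optional per-base Phred qualities."""

    id: str
    bases: str
    qualities: np.ndarray | None = None
    sample: str | None = None
    fate: str | None = None  # "pass" or one of REJECT_REASONS
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, dtype=int)
            if len(self.qualities) != len(self.bases):
                raise ValueError(
                    f"read {self.id}: {len(self.bases)} bases but "
                    f"{len(self.qualities)} quality scores"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        if self.qualities is None:
            raise ValueError(f"read {self.id} has no quality data")
        return float(np.mean(self.qualities))


@dataclass
class QcPolicy:
    """Read-curation thresholds.

    Defaults mirror the standard 454 16S curation rules: drop reads shorter
    than 200 nt or longer than 600 nt, with mean quality below 25, containing
    ambiguous bases, with a non-exact barcode, or with more than 4 mismatches
    to the reverse primer.
    """

    min_len: int = 200
    max_len: int = 600
    min_mean_quality: float = 25.0
    allow_ambiguous: bool = False
    barcode_exact: bool = True
    max_reverse_primer_mismatches: int = 4
    forward_primer: str = "CCTACGGGAGGCAGCAG"   # 357F
    reverse_primer: str = "CCGTCAATTCMTTTRAGT"  # 926R
    barcode_map: dict[str, str] = field(default_factory=dict)
    require_quality: bool = True
    length_after_trim: bool = False  # default: length rule on the raw read

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ConfigurationError(
                f"min_len ({self.min_len}) > max_len ({self.max_len})")
        if self.max_reverse_primer_mismatches < 0:
            raise ConfigurationError("mismatch budget must be >= 0")
        validate_barcodes(self.barcode_map)


def validate_barcodes(barcode_map: dict[str, str]) -> None:
    """Barcodes must be non-empty and prefix-free (no barcode a prefix of another)."""
    codes = list(barcode_map)
    for b in codes:
        if not b:
            raise ConfigurationError("empty barcode in barcode map")
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            if a.startswith(b) or b.startswith(a):
                raise ConfigurationError(
                    f"barcodes {a!r} and {b!r} are prefixes of one another")


def iupac_mismatches(observed: str, pattern: str) -> int:
    """Count mismatches of ``observed`` against an IUPAC ``pattern``.

    Degeneracy is honored on the pattern (primer) side only; an N in the read
    matches nothing.
    """
    n = 0
    for obs, pat in zip(observed, pattern):
        if obs not in "ACGT" or obs not in IUPAC.get(pat, set()):
            n += 1
    n += abs(len(observed) - len(pattern))
    return n


def locate_reverse_primer(bases: str, primer: str) -> tuple[int, int]:
    """Best ungapped placement of the reverse primer near the 3' end.

    Searches the final ``ceil(1.5 * len(primer))`` nt window and returns
    ``(start, mismatches)`` for the placement with fewest mismatches
    (rightmost wins ties).  If the read is shorter than the primer the whole
    primer counts as mismatched.
    """
    plen = len(primer)
    if len(bases) < plen:
        return 0, plen
    window = int(np.ceil(1.5 * plen))
    lo = max(0, len(bases) - window)
    best_start, best_mm = lo, plen + 1
    for start in range(lo, len(bases) - plen + 1):
        mm = iupac_mismatches(bases[start:start + plen], primer)
        if mm <= best_mm:
            best_start, best_mm = start, mm
    return best_start, best_mm


def demultiplex(reads: Iterable[AmpliconRead], policy: QcPolicy) -> list[AmpliconRead]:
    """Assign reads to samples by exact 5' barcode match and trim the barcode.

    Reads whose 5' end matches no barcode get ``fate='reject'`` with reason
    ``barcode_mismatch``.
    """
    if not policy.barcode_map:
        raise ConfigurationError("barcode map is empty")
    validate_barcodes(policy.barcode_map)
    out = []
    for read in reads:
        hit = None
        for barcode, sample in policy.barcode_map.items():
            if read.bases.startswith(barcode):
                hit = (barcode, sample)
                break
        if hit is None:
            out.append(replace(read, fate="reject", reason="barcode_mismatch"))
            continue
        barcode, sample = hit
        n = len(barcode)
        quals = read.qualities[n:] if read.qualities is not None else None
        out.append(replace(read, bases=read.bases[n:], qualities=quals,
                           sample=sample))
    return out


def filter_read(read: AmpliconRead, policy: QcPolicy) -> AmpliconRead:
    """Apply the curation rules in fixed order and record the first violation.

    A passing read is returned with the forward primer trimmed from the 5' end
    (when it matches within 2 IUPAC mismatches) and the read truncated at the
    located reverse primer.
    """
    if read.fate == "reject":
        return read
    if read.fate == "pass":
        # already filtered and trimmed; re-filtering is a no-op (idempotence)
        return read
    if len(read) < policy.min_len:
        return replace(read, fate="reject", reason="too_short")
    if len(read) > policy.max_len:
        return replace(read, fate="reject", reason="too_long")
    if policy.min_mean_quality > 0:
        if read.qualities is None:
            if policy.require_quality:
                raise ValueError(
                    f"read {read.id}: no quality data but policy requires "
                    f"mean quality >= {policy.min_mean_quality}")
        elif read.mean_quality < policy.min_mean_quality:
            return replace(read, fate="reject", reason="low_quality")
    if not policy.allow_ambiguous and any(b not in "ACGT" for b in read.bases):
        return replace(read, fate="reject", reason="ambiguous")

    start, mm = locate_reverse_primer(read.bases, policy.reverse_primer)
    if mm > policy.max_reverse_primer_mismatches:
        return replace(read, fate="reject", reason="primer_mismatch")

    # trim: forward primer (lenient match; not a rejection rule) and the
    # 3' region from the reverse primer on
    bases, quals = read.bases[:start], read.qualities
    if quals is not None:
        quals = quals[:start]
    fwd = policy.forward_primer
    if fwd and len(bases) >= len(fwd) and iupac_mismatches(bases[:len(fwd)], fwd) <= 2:
        bases = bases[len(fwd):]
        if quals is not None:
            quals = quals[len(fwd):]
    return replace(read, bases=bases, qualities=quals, fate="pass", reason=None)


def run_qc(
    reads: Sequence[AmpliconRead],
    policy: QcPolicy,
    demultiplex_stage: bool = True,
) -> tuple[list[AmpliconRead], pd.DataFrame, dict]:
    """Demultiplex (optionally) and filter a read pool.

    Returns ``(processed_reads, fate_log, summary)``.  The fate log has one
    row per input read (read_id, sample, fate, reason); the summary counts
    satisfy ``passed + sum(rejections) == total``.
    """
    reads = list(reads)
    if demultiplex_stage:
        staged = demultiplex(reads, policy)
    else:
        staged = list(reads)
    processed = [filter_read(r, policy) for r in staged]
    log = pd.DataFrame(
        {
            "read_id": [r.id for r in processed],
            "sample": [r.sample for r in processed],
            "fate": ["pass" if r.fate == "pass" else "reject" for r in processed],
            "reason": [r.reason for r in processed],
        }
    )
    summary = {
        "total": len(processed),
        "passed": int((log["fate"] == "pass").sum()),
        "rejected": {
            reason: int((log["reason"] == reason).sum())
            for reason in REJECT_REASONS
        },
    }
    assert summary["passed"] + sum(summary["rejected"].values()) == summary["total"]
    return processed, log, summary


def apply_chimera_report(
    reads: Sequence[AmpliconRead], report_file: str | Path
) -> list[AmpliconRead]:
    """Reject reads named in an external chimera report (one id per line).

    The first whitespace-separated token of each non-empty line is a read id.
    Ids not present in the read set are logged and ignored.
    """
    listed: set[str] = set()
    with open(report_file) as fh:
        for line in fh:
            tok = line.split()
            if tok:
                listed.add(tok[0])
    known = {r.id for r in reads}
    for missing in sorted(listed - known):
        logger.warning("chimera report names unknown read id %r", missing)
    return [
        replace(r, fate="reject", reason="chimeric") if r.id in listed else r
        for r in reads
    ]


# ---------------------------------------------------------------------------
# file I/O


def _to_record(read: AmpliconRead) -> SeqRecord:
    rec = SeqRecord(Seq(read.bases), id=read.id, description="")
    if read.qualities is not None:
        rec.letter_annotations["phred_quality"] = [int(q) for q in read.qualities]
    return rec


def _from_record(rec: SeqRecord) -> AmpliconRead:
    quals = rec.letter_annotations.get("phred_quality")
    return AmpliconRead(
        id=rec.id,
        bases=str(rec.seq).upper(),
        qualities=None if quals is None else np.asarray(quals, dtype=int),
    )


def read_fastq(path: str | Path) -> list[AmpliconRead]:
    """Load reads from a FASTQ file (Sanger offset 33)."""
    return [_from_record(rec) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta_qual(fasta: str | Path, qual: str | Path | None = None) -> list[AmpliconRead]:
    """Load reads from a FASTA file, optionally paired with a '.qual' file."""
    if qual is None:
        return [_from_record(rec) for rec in SeqIO.parse(str(fasta), "fasta")]
    with open(fasta) as fa, open(qual) as qf:
        return [_from_record(rec) for rec in PairedFastaQualIterator(fa, qf)]


def write_fastq(reads: Iterable[AmpliconRead], path: str | Path) -> None:
    SeqIO.write((_to_record(r) for r in reads), str(path), "fastq")


def write_fasta_qual(
    reads: Iterable[AmpliconRead], fasta: str | Path, qual: str | Path | None = None
) -> None:
    reads = list(reads)
    SeqIO.write((_to_record(r) for r in reads), str(fasta), "fasta")
    if qual is not None:
        if any(r.qualities is None for r in reads):
            warnings.warn("some reads lack qualities; .qual file omitted")
        else:
            SeqIO.write((_to_record(r) for r in reads), str(qual), "qual")
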