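"""Synthetic cohorts and multiplexed amplicon reads with known ground truth.

The cohort generator emulates a 454-era 16S case-control survey: per-sample
taxa proportions are Dirichlet draws around a shared power-law baseline (a
few dominant taxa, a long tail of sub-1% taxa), sequencing depth is
negative-binomial around 2690 reads/sample (dispersion chosen so the spread
matches the ~900-read scatter typical of such runs), and disease effects are
planted on a chosen subset of taxa by scaling their proportions by
``2**lfc`` in the case class and renormalizing (compositional by
construction).  An optional per-class multiplier on the Dirichlet
concentration models the loss of diversity seen in severe disease.

The read simulator turns a cohort into a multiplexed read pool: each read is
``barcode + forward primer + 16S template substring + reverse primer`` with
per-base errors and synthetic quality strings, and a configurable fraction
of reads is deliberately corrupted to violate each QC rule.  Ground truth
(sample, source genus, planted defect) is recorded in every read header, so
QC and taxonomy accuracy can be audited exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .qc import IUPAC, AmpliconRead
from .taxonomy import DEFAULT_RANKS, ReferenceDB

CORRUPTION_KINDS = ("too_short", "too_long", "low_quality", "ambiguous",
                    "barcode_mismatch", "primer_mismatch")


class ParameterError(ValueError):
    """Invalid simulation parameter; the message names the offending field."""


@dataclass
class CohortSpec:
    """Conditions of a simulated case-control cohort.

    ``planted_taxa`` lists ``(taxon_index, log2 fold change)`` effects applied
    in the case class.  ``baseline_concentration`` gives the Dirichlet
    parameters directly; by default a power-law baseline with total
    concentration 300 is used so that most taxa sit below 1% relative
    abundance.  ``diversity_gradient`` maps a label to a multiplier on the
    concentration vector (multipliers < 1 lower the expected Shannon
    diversity of that class).
    """

    n_per_class: dict[str, int] = field(default_factory=lambda: {"control": 24, "IBD": 67})
    n_taxa: int = 200
    planted_taxa: list[tuple[int, float]] = field(default_factory=list)
    baseline_concentration: np.ndarray | None = None
    depth_mean: float = 2690.0
    depth_dispersion: float = 9.0
    diversity_gradient: dict[str, float] | None = None
    case_label: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_class) < 1:
            raise ParameterError("n_per_class: need at least one label")
        for label, n in self.n_per_class.items():
            if n < 2:
                raise ParameterError(f"n_per_class[{label!r}]: need >= 2 samples, got {n}")
        if self.n_taxa < 1:
            raise ParameterError(f"n_taxa: must be positive, got {self.n_taxa}")
        idx = [i for i, _ in self.planted_taxa]
        if len(set(idx)) != len(idx):
            raise ParameterError("planted_taxa: indices must be distinct")
        for i in idx:
            if not 0 <= i < self.n_taxa:
                raise ParameterError(f"planted_taxa: index {i} outside [0, {self.n_taxa})")
        if self.depth_mean <= 0:
            raise ParameterError(f"depth_mean: must be > 0, got {self.depth_mean}")
        if self.depth_dispersion <= 0:
            raise ParameterError(f"depth_dispersion: must be > 0, got {self.depth_dispersion}")
        if self.baseline_concentration is not None:
            a = np.asarray(self.baseline_concentration, dtype=float)
            if a.shape != (self.n_taxa,):
                raise ParameterError("baseline_concentration: length must equal n_taxa")
            if (a <= 0).any():
                raise ParameterError("baseline_concentration: entries must be positive")
        if self.case_label is not None and self.case_label not in self.n_per_class:
            raise ParameterError(f"case_label: {self.case_label!r} not among labels")
        if self.diversity_gradient:
            for label, mult in self.diversity_gradient.items():
                if mult <= 0:
                    raise ParameterError(f"diversity_gradient[{label!r}]: must be > 0")

    @property
    def resolved_case_label(self) -> str:
        if self.case_label is not None:
            return self.case_label
        return list(self.n_per_class)[-1]

    def concentration(self) -> np.ndarray:
        if self.baseline_concentration is not None:
            return np.asarray(self.baseline_concentration, dtype=float)
        return default_concentration(self.n_taxa)


def default_concentration(n_taxa: int, total: float = 300.0) -> np.ndarray:
    """Power-law Dirichlet baseline: alpha_i proportional to 1/(i+1).

    With 200 taxa the expected relative abundance of the leading taxon is
    about 17% and taxa beyond rank ~30 sit below 1%, matching the long tail
    of low-abundance taxa in real gut surveys.  The total concentration sets
    between-sample variability (a 1% taxon has a between-sample CV of about
    0.6 at the default), moderate overdispersion typical of case-control
    cohorts after removing outlier samples.
    """
    w = 1.0 / np.arange(1, n_taxa + 1)
    return total * w / w.sum()


def default_planted(n_effects: int = 10, lfc: float = 1.5,
                    start: int = 5, step: int = 5) -> list[tuple[int, float]]:
    """Evenly spaced planted effects with alternating sign, |lfc| fixed."""
    return [(start + i * step, lfc if i % 2 == 0 else -lfc)
            for i in range(n_effects)]


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    planted: pd.DataFrame          # taxon, lfc
    proportions: pd.DataFrame      # taxa x samples, true (post-effect) proportions


def simulate_cohort(spec: CohortSpec) -> tuple[AbundanceTable, pd.Series, CohortTruth]:
    """Draw a labeled taxa-by-sample count table from the cohort model.

    Per sample: proportions ~ Dirichlet(class concentration); in the case
    class the planted components are scaled by ``2**lfc`` and renormalized;
    depth ~ negative binomial(depth_mean, depth_dispersion), floored at 1;
    counts ~ multinomial(depth, proportions).  Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alpha = spec.concentration()
    case = spec.resolved_case_label
    taxa = [f"taxon_{i:04d}" for i in range(spec.n_taxa)]

    sample_ids, labels = [], []
    for label, n in spec.n_per_class.items():
        for j in range(n):
            sample_ids.append(f"{label}_{j:03d}")
            labels.append(label)
    labels = pd.Series(labels, index=sample_ids, name="label")

    nb_p = spec.depth_dispersion / (spec.depth_dispersion + spec.depth_mean)
    props = np.empty((spec.n_taxa, len(sample_ids)))
    counts = np.empty_like(props, dtype=int)
    for si, (sid, label) in enumerate(zip(sample_ids, labels)):
        a = alpha
        if spec.diversity_gradient and label in spec.diversity_gradient:
            a = alpha * spec.diversity_gradient[label]
        p = rng.dirichlet(a)
        if label == case:
            for ti, lfc in spec.planted_taxa:
                p[ti] *= 2.0 ** lfc
            p = p / p.sum()
        depth = max(1, int(rng.negative_binomial(spec.depth_dispersion, nb_p)))
        props[:, si] = p
        counts[:, si] = rng.multinomial(depth, p)

    counts_df = pd.DataFrame(counts, index=taxa, columns=sample_ids)
    meta = labels.to_frame()
    table = AbundanceTable(counts=counts_df, metadata=meta)
    truth = CohortTruth(
        planted=pd.DataFrame(
            [(taxa[i], lfc) for i, lfc in spec.planted_taxa],
            columns=["taxon", "lfc"]),
        proportions=pd.DataFrame(props, index=taxa, columns=sample_ids),
    )
    return table, labels, truth


# ---------------------------------------------------------------------------
# reference sequences and read-level simulation


def synthetic_reference(
    n_genera: int = 5,
    seqs_per_genus: int = 3,
    length: int = 900,
    divergence: float = 0.02,
    seed: int = 0,
) -> ReferenceDB:
    """Well-separated synthetic 16S-like reference sequences with lineages.

    Each genus gets an independent random base sequence; within-genus copies
    differ by ``divergence`` point substitutions.  Genera are nested into
    deterministic higher ranks (two genera per family, two families per
    class/phylum block) so multi-rank tables exercise the full hierarchy.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []
    for g in range(n_genera):
        base = rng.integers(0, 4, size=length)
        lineage = (
            "Bacteria",
            f"Phylum_{g // 8:02d}",
            f"Class_{g // 4:02d}",
            f"Order_{g // 4:02d}",
            f"Family_{g // 2:02d}",
            f"Genus_{g:02d}",
        )
        for s in range(seqs_per_genus):
            seq = base.copy()
            n_mut = rng.binomial(length, divergence)
            pos = rng.choice(length, size=n_mut, replace=False)
            seq[pos] = (seq[pos] + rng.integers(1, 4, size=n_mut)) % 4
            records.append((f"ref_g{g:02d}_s{s:02d}", "".join(bases[seq]), lineage))
    return ReferenceDB(records, DEFAULT_RANKS)


def random_barcodes(samples: list[str], length: int = 8, seed: int = 0) -> dict[str, str]:
    """Unique fixed-length barcodes (same length => prefix-free) per sample."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    codes: dict[str, str] = {}
    used = set()
    for s in samples:
        while True:
            code = "".join(rng.choice(list(bases), size=length))
            if code not in used:
                used.add(code)
                codes[code] = s
                break
    return codes


@dataclass
class ReadSimSpec:
    """Conditions of the read-level simulation."""

    cohort: CohortSpec
    reference: ReferenceDB
    barcode_map: dict[str, str] | None = None   # barcode -> sample; auto if None
    forward_primer: str = "CCTACGGGAGGCAGCAG"   # 357F
    reverse_primer: str = "CCGTCAATTCMTTTRAGT"  # 926R
    read_length_range: tuple[int, int] = (300, 450)  # template nt
    per_base_error: float = 0.0
    quality_mean: float = 35.0
    quality_sd: float = 4.0
    corruption: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        if not self.forward_primer or not self.reverse_primer:
            raise ParameterError("primers must be non-empty")
        lo, hi = self.read_length_range
        if not 0 < lo <= hi:
            raise ParameterError("read_length_range: need 0 < min <= max")
        if not 0 <= self.per_base_error < 1:
            raise ParameterError("per_base_error: must lie in [0, 1)")
        for kind, frac in self.corruption.items():
            if kind not in CORRUPTION_KINDS:
                raise ParameterError(f"corruption: unknown kind {kind!r}")
            if not 0 <= frac <= 1:
                raise ParameterError(f"corruption[{kind!r}]: fraction outside [0, 1]")
        genera = self.reference.genera
        if self.cohort.n_taxa > len(genera):
            raise ParameterError(
                f"reference: cohort has {self.cohort.n_taxa} taxa but the "
                f"reference provides only {len(genera)} genera")
        if self.barcode_map is not None:
            if len(set(self.barcode_map.values())) != len(self.barcode_map):
                raise ParameterError("barcode_map: barcodes must be unique per sample")


@dataclass
class ReadSimResult:
    """Simulated read pool plus full ground truth."""

    reads: list[AmpliconRead]
    barcode_map: dict[str, str]
    truth_proportions: pd.DataFrame   # genus x sample, true proportions
    read_truth: pd.DataFrame          # read_id, sample, genus, defect
    labels: pd.Series


def _instantiate_primer(primer: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC degeneracies to concrete bases."""
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC[b])) for b in primer)


def _mutate(seq: str, n_mut: int, rng: np.random.Generator,
            alphabet: str = "ACGT") -> str:
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in alphabet if b != out[p]])
    return "".join(out)


def _corrupt_primer(primer_instance: str, iupac_pattern: str, n_mismatch: int,
                    rng: np.random.Generator) -> str:
    """Plant exactly ``n_mismatch`` IUPAC-aware mismatches into a primer copy.

    Mutated positions are set to bases outside the IUPAC expansion of the
    pattern, so each one counts as a true mismatch under the QC rule.
    """
    pos = rng.choice(len(primer_instance), size=n_mismatch, replace=False)
    out = list(primer_instance)
    for p in pos:
        allowed = IUPAC[iupac_pattern[p]]
        out[p] = rng.choice(sorted(set("ACGT") - allowed))
    return "".join(out)


def simulate_reads(spec: ReadSimSpec) -> ReadSimResult:
    """Generate a multiplexed pool of amplicon reads from a cohort.

    Cohort taxon ``i`` maps to the reference's ``i``-th genus.  Clean reads
    pass every QC rule by construction; each corruption kind is planted into
    its configured fraction of reads (disjointly, in the order of
    ``CORRUPTION_KINDS``) and recorded in the read id as ``defect=<kind>``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cohort_rng_spec = spec.cohort
    table, labels, truth = simulate_cohort(cohort_rng_spec)

    genera = spec.reference.genera[: spec.cohort.n_taxa]
    by_genus: dict[str, list[str]] = {g: [] for g in genera}
    for _, seq, lineage in spec.reference.records:
        if lineage[-1] in by_genus:
            by_genus[lineage[-1]].append(seq)

    barcode_map = spec.barcode_map or random_barcodes(
        list(table.samples), seed=spec.seed + 1)
    sample_barcode = {s: b for b, s in barcode_map.items()}

    # build clean reads
    reads_meta: list[tuple[str, str]] = []   # (sample, genus) per read
    for sample in table.samples:
        col = table.counts[sample]
        for ti, genus in enumerate(genera):
            reads_meta.extend([(sample, genus)] * int(col.iloc[ti]))
    n_reads = len(reads_meta)

    # assign defects disjointly
    defects = np.array(["none"] * n_reads, dtype=object)
    free = list(range(n_reads))
    rng.shuffle(free)
    cursor = 0
    for kind in CORRUPTION_KINDS:
        frac = spec.corruption.get(kind, 0.0)
        n_kind = int(round(frac * n_reads))
        for idx in free[cursor:cursor + n_kind]:
            defects[idx] = kind
        cursor += n_kind

    lo, hi = spec.read_length_range
    fwd_len, rev_len = len(spec.forward_primer), len(spec.reverse_primer)
    reads: list[AmpliconRead] = []
    truth_rows = []
    for i, (sample, genus) in enumerate(reads_meta):
        defect = str(defects[i])
        barcode = sample_barcode[sample]
        template_src = by_genus[genus][rng.integers(0, len(by_genus[genus]))]
        tlen = int(rng.integers(lo, hi + 1))
        tlen = min(tlen, len(template_src))
        start = int(rng.integers(0, len(template_src) - tlen + 1))
        template = template_src[start:start + tlen]
        if spec.per_base_error > 0:
            n_err = rng.binomial(tlen, spec.per_base_error)
            if n_err:
                template = _mutate(template, n_err, rng)
        fwd = _instantiate_primer(spec.forward_primer, rng)
        rev = _instantiate_primer(spec.reverse_primer, rng)
        qmean = spec.quality_mean

        if defect == "too_short":
            # post-barcode length below min_len=200 incl. primers
            template = template[: max(1, 150 - fwd_len - rev_len)]
        elif defect == "too_long":
            extra = "".join(rng.choice(list("ACGT"), size=650))
            template = (template + extra)[:650]
        elif defect == "low_quality":
            qmean = 15.0
        elif defect == "ambiguous":
            mid = len(template) // 2
            template = template[:mid] + "N" + template[mid + 1:]
        elif defect == "barcode_mismatch":
            while True:
                bad = _mutate(barcode, 1, rng)
                if not any(bad.startswith(bc) or bc.startswith(bad)
                           for bc in barcode_map):
                    barcode = bad
                    break
        elif defect == "primer_mismatch":
            rev = _corrupt_primer(rev, spec.reverse_primer, 5, rng)

        bases = barcode + fwd + template + rev
        quals = np.clip(np.rint(rng.normal(qmean, spec.quality_sd, size=len(bases))),
                        2, 41).astype(int)
        rid = f"read_{i:06d};sample={sample};genus={genus};defect={defect}"
        reads.append(AmpliconRead(id=rid, bases=bases, qualities=quals))
        truth_rows.append({"read_id": rid, "sample": sample,
                           "genus": genus, "defect": defect})

    props = truth.proportions.copy()
    props.index = genera
    return ReadSimResult(
        reads=reads,
        barcode_map=barcode_map,
        truth_proportions=props,
        read_truth=pd.DataFrame(truth_rows),
        labels=labels,
    )


def designed_defect_fixture(seed: int = 42):
    """Ten hand-designed reads: four clean passes, six single-rule violations.

    Exercises every QC rejection reason once (too short, too long, low mean
    quality, ambiguous base, non-exact barcode, 5 reverse-primer mismatches)
    plus the 4-mismatch reverse-primer boundary on one passing read.

    Returns ``(reads, barcode_map, expected)`` where ``expected`` maps read
    id to ``'pass'`` or the rejection reason.
    """
    rng = np.random.default_rng(seed)
    fwd = "CCTACGGGAGGCAGCAG"           # 357F
    rev_instance = "CCGTCAATTCATTTAAGT"  # one expansion of 926R (M->A, R->A)
    barcode_map = {"AAAA": "S1", "CCCC": "S2"}

    def tmpl(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    def read(rid, template, barcode="AAAA", rev=rev_instance, qual=30):
        bases = barcode + fwd + template + rev
        return AmpliconRead(id=rid, bases=bases,
                            qualities=np.full(len(bases), qual, dtype=int))

    rev4 = "AAAA" + rev_instance[4:]    # 4 mismatches at non-degenerate sites
    rev5 = "AAAAA" + rev_instance[5:]   # 5 mismatches
    reads = [
        read("ok_1", tmpl(250)),
        read("ok_2", tmpl(300), barcode="CCCC"),
        read("ok_3", tmpl(400)),
        read("ok_4mm", tmpl(250), rev=rev4),
        read("short", tmpl(100)),            # 135 nt after barcode < 200
        read("long", tmpl(600)),             # 635 nt after barcode > 600
        read("lowq", tmpl(250), qual=20),    # mean quality 20 < 25
        read("ambig", tmpl(120) + "N" + tmpl(129)),
        read("badbc", tmpl(250), barcode="GGGG"),
        read("rev5mm", tmpl(250), rev=rev5),
    ]
    expected = {
        "ok_1": "pass", "ok_2": "pass", "ok_3": "pass", "ok_4mm": "pass",
        "short": "too_short", "long": "too_long", "lowq": "low_quality",
        "ambig": "ambiguous", "badbc": "barcode_mismatch",
        "rev5mm": "primer_mismatch",
    }
    return reads, barcode_map, expected
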