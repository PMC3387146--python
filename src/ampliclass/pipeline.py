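"""End-to-end pipeline orchestration: simulate -> QC -> taxonomy -> table -> stats + CV.

A run is driven by a nested key/value config (YAML on disk).  Stages write
TSV/JSON outputs into the run directory, and a manifest records the master
seed, package versions and a SHA-256 digest of every output file.  Rerunning
with the same config and seed reproduces every statistical output
byte-for-byte.

Config sections (all optional except ``seed`` and ``outdir`` when run from
the CLI)::

    seed: 0
    outdir: runs/demo
    simulate:
      mode: counts          # counts | reads
      n_per_class: {control: 60, IBD: 60}
      n_taxa: 200
      planted: {n_effects: 10, lfc: 1.5}
      depth_mean: 2690
    qc: {min_len: 200, max_len: 600, min_mean_quality: 25}
    taxonomy: {word_size: 8, n_bootstrap: 100, confidence_threshold: 0.8}
    tabulate: {ranks: [phylum, class, order, family, genus]}
    assoc: {label: label, q_threshold: 0.05}
    cv: {k: 10, repeats: 3, n_trees: 500, target_sensitivity: 0.8}
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import AbundanceTable, attach_diversity, normalize, sample_diversity, tabulate
from .classify import ClassifierSpec, choose_operating_point, confusion_at, cross_validate
from .qc import QcPolicy, run_qc, write_fasta_qual
from .stats import associate_features
from .synthetic import (CohortSpec, ReadSimSpec, default_planted,
                        simulate_cohort, simulate_reads, synthetic_reference)
from .taxonomy import assign_all, train

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration invalid; message aggregates all problems found."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def validate_config(config: dict) -> list[str]:
    """Schema and cross-field checks; returns all problems at once.

    Entries starting with ``warning:`` are advisory; anything else is fatal.
    Never touches read data.
    """
    issues: list[str] = []
    sim = config.get("simulate", {})
    mode = sim.get("mode", "counts")
    if mode not in ("counts", "reads"):
        issues.append(f"simulate.mode: expected 'counts' or 'reads', got {mode!r}")
    if sim:
        try:
            _cohort_spec(config).validate()
        except Exception as exc:
            issues.append(f"simulate: {exc}")
    else:
        for key in ("counts", "metadata"):
            p = config.get("inputs", {}).get(key)
            if p is None:
                issues.append(f"inputs.{key}: required when no simulate section is given")
            elif not Path(p).exists():
                issues.append(f"inputs.{key}: file {p!r} does not exist")
    qc = config.get("qc", {})
    if qc.get("barcodes") is not None and not Path(qc["barcodes"]).exists():
        issues.append(f"qc.barcodes: file {qc['barcodes']!r} does not exist")
    cv = config.get("cv", {})
    k = int(cv.get("k", 10))
    if k < 2:
        issues.append(f"cv.k: need >= 2 folds, got {k}")
    if sim:
        try:
            n_min = min(int(n) for n in _cohort_spec(config).n_per_class.values())
            if n_min < k:
                issues.append(
                    f"warning: cv.k={k} folds with only {n_min} samples in the "
                    "smallest class; stratified folds will fail")
        except Exception:
            pass
    if int(cv.get("n_trees", 500)) < 1:
        issues.append("cv.n_trees: must be >= 1")
    return issues


def _cohort_spec(config: dict) -> CohortSpec:
    sim = config.get("simulate", {})
    planted = sim.get("planted", {})
    n_taxa = int(sim.get("n_taxa", 200))
    if isinstance(planted, dict):
        n_eff = int(planted.get("n_effects", 0))
        lfc = float(planted.get("lfc", 1.5))
        if n_eff == 0:
            planted_list = []
        elif n_taxa > 55:
            planted_list = default_planted(n_effects=n_eff, lfc=lfc)
        else:  # small taxa panels: spread effects over the available range
            idx = np.unique(np.linspace(1, max(1, n_taxa - 1), n_eff)
                            .round().astype(int))
            planted_list = [(int(i), lfc if j % 2 == 0 else -lfc)
                            for j, i in enumerate(idx)]
    else:
        planted_list = [(int(i), float(l)) for i, l in planted]
    return CohortSpec(
        n_per_class={str(k): int(v) for k, v in
                     sim.get("n_per_class", {"control": 60, "IBD": 60}).items()},
        n_taxa=n_taxa,
        planted_taxa=planted_list,
        depth_mean=float(sim.get("depth_mean", 2690.0)),
        depth_dispersion=float(sim.get("depth_dispersion", 9.0)),
        diversity_gradient=sim.get("diversity_gradient"),
        seed=int(config.get("seed", 0)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir: str | Path | None = None) -> Path:
    """Execute the configured stages in order and write a manifest.

    Returns the run directory.  A failing stage raises with the stage named;
    outputs of completed stages are retained.
    """
    issues = [i for i in validate_config(config) if not i.startswith("warning:")]
    if issues:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(issues))
    outdir = Path(outdir or config.get("outdir", "ampliclass_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stage = "setup"
    summary_lines = [f"ampliclass {__version__} run, seed={seed}"]
    try:
        # ------------------------------------------------ stage: table
        stage = "simulate"
        sim = config.get("simulate", {})
        mode = sim.get("mode", "counts")
        if sim and mode == "reads":
            table, labels = _simulate_reads_stage(config, outdir, seed, summary_lines)
        elif sim:
            spec = _cohort_spec(config)
            table, labels, truth = simulate_cohort(spec)
            truth.planted.to_csv(outdir / "truth_planted.tsv", sep="\t", index=False)
            truth.proportions.to_csv(outdir / "truth_proportions.tsv", sep="\t")
            summary_lines.append(
                f"simulated cohort: {len(table.samples)} samples, "
                f"{len(table.features)} taxa, {len(spec.planted_taxa)} planted effects")
        else:
            stage = "load"
            table = AbundanceTable.from_tsv(config["inputs"]["counts"],
                                            config["inputs"]["metadata"])
        table.to_tsv(outdir / "counts.tsv", outdir / "metadata.tsv")

        stage = "normalize"
        table = normalize(table)
        div = sample_diversity(table, rank="genus" if table.ranks is not None else None)
        div.to_csv(outdir / "diversity.tsv", sep="\t", header=True)
        if config.get("cv", {}).get("use_diversity", False):
            table = attach_diversity(
                table, rank="genus" if table.ranks is not None else None)

        # ------------------------------------------------ stage: association
        stage = "assoc"
        assoc_cfg = config.get("assoc", {})
        label_field = assoc_cfg.get("label", "label")
        q_thr = float(assoc_cfg.get("q_threshold", 0.05))
        assoc, pi0 = associate_features(table, label_field, q_threshold=q_thr)
        assoc.to_csv(outdir / "association.tsv", sep="\t")
        n_sig = int(assoc["significant"].sum())
        summary_lines.append(
            f"association: {n_sig} features significant at q<{q_thr} "
            f"(pi0_hat={pi0:.3f})")

        # ------------------------------------------------ stage: cross-validation
        stage = "cv"
        cv_cfg = config.get("cv", {})
        spec = ClassifierSpec(n_trees=int(cv_cfg.get("n_trees", 500)),
                              positive_class=cv_cfg.get("positive_class"))
        ev = cross_validate(table, label_field, spec,
                            k=int(cv_cfg.get("k", 10)),
                            repeats=int(cv_cfg.get("repeats", 3)), seed=seed)
        ev.roc.to_csv(outdir / "roc.tsv", sep="\t", index=False)
        ev.scores.to_csv(outdir / "cv_scores.tsv", sep="\t")
        thr, sens, spec_ = choose_operating_point(
            ev.roc, float(cv_cfg.get("target_sensitivity", 0.8)))
        med_scores = ev.scores.iloc[:, int(np.argsort(ev.aucs)[len(ev.aucs) // 2])]
        conf = confusion_at(med_scores.to_numpy(), ev.labels.to_numpy(), thr,
                            ev.positive_class)
        auc_summary = {
            "aucs": ev.aucs, "auc_median": ev.auc_median,
            "positive_class": ev.positive_class,
            "operating_point": {"threshold": thr, "sensitivity": sens,
                                "specificity": spec_},
            "confusion": conf,
        }
        (outdir / "auc_summary.json").write_text(json.dumps(auc_summary, indent=2))
        summary_lines.append(
            f"cross-validation: median AUC {ev.auc_median:.3f} over "
            f"{len(ev.aucs)} repeats of {int(cv_cfg.get('k', 10))}-fold CV")
        summary_lines.append(
            f"operating point: threshold {thr:.3f} -> sensitivity {sens:.3f}, "
            f"specificity {spec_:.3f}")
        top = assoc.head(5).index.tolist()
        summary_lines.append("top associated features: " + ", ".join(top))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    manifest = {
        "package": "ampliclass",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "config": config,
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _simulate_reads_stage(config: dict, outdir: Path, seed: int,
                          summary_lines: list[str]):
    """reads-mode front end: simulate reads, QC, classify, tabulate."""
    sim = config.get("simulate", {})
    cohort = _cohort_spec(config)
    ref = synthetic_reference(
        n_genera=max(cohort.n_taxa, int(sim.get("n_genera", cohort.n_taxa))),
        seed=seed + 17)
    rspec = ReadSimSpec(
        cohort=cohort, reference=ref,
        per_base_error=float(sim.get("per_base_error", 0.0)),
        corruption=sim.get("corruption", {}) or {},
        seed=seed)
    result = simulate_reads(rspec)
    write_fasta_qual(result.reads, outdir / "reads.fasta", outdir / "reads.qual")
    pd.Series(result.barcode_map, name="sample").rename_axis("barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t")
    result.read_truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
    result.truth_proportions.to_csv(outdir / "truth_proportions.tsv", sep="\t")
    summary_lines.append(f"simulated reads: {len(result.reads)} over "
                         f"{len(result.truth_proportions.columns)} samples")

    qc_cfg = config.get("qc", {})
    policy = QcPolicy(
        min_len=int(qc_cfg.get("min_len", 200)),
        max_len=int(qc_cfg.get("max_len", 600)),
        min_mean_quality=float(qc_cfg.get("min_mean_quality", 25)),
        max_reverse_primer_mismatches=int(qc_cfg.get("max_reverse_primer_mismatches", 4)),
        forward_primer=rspec.forward_primer,
        reverse_primer=rspec.reverse_primer,
        barcode_map=result.barcode_map)
    processed, fate_log, qc_summary = run_qc(result.reads, policy)
    fate_log.to_csv(outdir / "qc_fates.tsv", sep="\t", index=False)
    (outdir / "qc_summary.json").write_text(json.dumps(qc_summary, indent=2))
    summary_lines.append(
        f"qc: {qc_summary['passed']}/{qc_summary['total']} reads passed")
    passed = [r for r in processed if r.fate == "pass"]

    tax_cfg = config.get("taxonomy", {})
    model = train(ref, word_size=int(tax_cfg.get("word_size", 8)))
    assignments = assign_all(
        model, passed,
        n_bootstrap=int(tax_cfg.get("n_bootstrap", 100)),
        confidence_threshold=float(tax_cfg.get("confidence_threshold", 0.8)),
        seed=seed)
    assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)

    ranks = config.get("tabulate", {}).get(
        "ranks", ["phylum", "class", "order", "family", "genus"])
    table = tabulate(assignments, ranks, samples=list(result.labels.index))
    meta = result.labels.to_frame()
    table.metadata = meta.loc[table.samples]
    return table, result.labels
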