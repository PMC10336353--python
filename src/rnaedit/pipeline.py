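"""End-to-end pipeline: simulate (optional) -> call -> filter -> annotate ->
differential -> summarize, with a provenance manifest.

Every stage writes its table under the output directory; the manifest records
the configuration, seed, thresholds, package version and the SHA-256 of every
emitted file, so re-running with an identical configuration yields an
identical manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_sites
from .differential import TestConfig, run_differential
from .filters import (FilterConfig, Tracks, apply_filter_cascade,
                      orient_candidates)
from .genes import read_gff3
from .io import (SampleSheet, read_bed, read_fasta, read_vcf_positions,
                 write_tsv)
from .pileup import CallThresholds, call_variants, load_alignments, observations_at
from .simulate import (EXPECTED_REMOVAL_REASON, SimConfig, TruthTable,
                       simulate_dataset)
from .summarize import (category_table, group_presence_venn, motif_matrix,
                        pca_editing, top_table)


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(out_dir: str | Path,
            sim_config: SimConfig | None = None,
            inputs: dict[str, str | Path] | None = None,
            thresholds: CallThresholds = CallThresholds(),
            filter_config: FilterConfig = FilterConfig(),
            test_config: TestConfig = TestConfig(),
            min_group_presence_level: float = 0.01,
            top_k: int = 50) -> dict:
    """Run the full pipeline; returns the manifest dict.

    Either ``sim_config`` (inputs are generated) or ``inputs`` (paths with
    keys genome, gff, repeats, dbsnp, known_editing, samples and sam:<sample>)
    must be given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- resolve inputs --------------------------------------------------
    if sim_config is not None:
        paths = simulate_dataset(sim_config, out_dir / "inputs")
    elif inputs is not None:
        paths = {k: Path(v) for k, v in inputs.items()}
    else:
        raise PipelineError("either sim_config or inputs is required")
    for key in ("genome", "gff", "repeats", "dbsnp", "known_editing", "samples"):
        if key not in paths or not Path(paths[key]).exists():
            raise PipelineError(f"missing required input: {key}")
    sam_keys = sorted(k for k in paths if k.startswith("sam:"))
    if not sam_keys:
        raise PipelineError("missing required input: per-sample SAM files")

    genome = read_fasta(paths["genome"])
    genes = read_gff3(paths["gff"], genome)
    repeats = read_bed(paths["repeats"], genome)
    dbsnp = read_vcf_positions(paths["dbsnp"])
    known = {(iv.chrom, iv.start) for iv in read_bed(paths["known_editing"])}
    sheet = SampleSheet.read_tsv(paths["samples"])

    # --- call -------------------------------------------------------------
    stores = {}
    for key in sam_keys:
        sample = key.split(":", 1)[1]
        if sample not in sheet.groups:
            raise PipelineError(f"SAM sample {sample!r} absent from sample sheet")
        stores[sample] = load_alignments(paths[key], genome)
    stores = {s: stores[s] for s in sheet.samples if s in stores}
    calls = call_variants(stores, genome, thresholds)

    # --- filter -----------------------------------------------------------
    candidates, ambiguous = orient_candidates(calls, genes, known)
    tracks = Tracks(repeats=repeats, dbsnp=dbsnp, known_editing=known)

    def obs_for(cand):
        return {s: observations_at(stores[s], cand.chrom, cand.pos)
                for s in stores}

    accepted, filter_log = apply_filter_cascade(
        candidates, genome, tracks, genes, obs_for, filter_config,
        min_bq=thresholds.min_base_quality)
    write_tsv(filter_log, out_dir / "filter_log.tsv")
    if len(ambiguous):
        write_tsv(ambiguous, out_dir / "ambiguous_strand.tsv")

    # --- annotate ----------------------------------------------------------
    annotated = annotate_sites(accepted, genes, genome, repeats)
    write_tsv(annotated, out_dir / "annotated_sites.tsv")

    # --- differential -----------------------------------------------------
    samples = sheet.samples
    alt = np.array([[s.alt_counts[s.samples.index(x)] for x in samples]
                    for s in accepted], dtype=float) \
        if accepted else np.zeros((0, len(samples)))
    ref = np.array([[s.ref_counts[s.samples.index(x)] for x in samples]
                    for s in accepted], dtype=float) \
        if accepted else np.zeros((0, len(samples)))
    site_ids = [s.site_id for s in accepted]
    diff = run_differential(alt, ref, samples, sheet, site_ids, test_config)
    diff.insert(1, "gene", [",".join(s.gene_ids) for s in accepted])
    write_tsv(diff, out_dir / "differential.tsv")
    write_tsv(diff[diff["is_dre"]].reset_index(drop=True),
              out_dir / "dre_sites.tsv")

    # --- summaries ---------------------------------------------------------
    outputs = {}
    if accepted:
        motif = motif_matrix(accepted, genome)
        motif.insert(0, "base", motif.index)
        write_tsv(motif, out_dir / "motif_matrix.tsv")
        write_tsv(category_table(annotated), out_dir / "category_table.tsv")
        write_tsv(group_presence_venn(annotated, sheet,
                                      min_group_presence_level),
                  out_dir / "venn.tsv")
        write_tsv(top_table(diff, top_k), out_dir / "top_dre.tsv")
        dre_mask = diff["is_dre"].to_numpy()
        if dre_mask.sum() >= 2:
            with np.errstate(invalid="ignore", divide="ignore"):
                lv = np.where(alt + ref > 0, alt / np.maximum(alt + ref, 1), 0.0)
            scores, frac = pca_editing(lv[dre_mask].T, samples)
            scores["group"] = [sheet.groups[s] for s in samples]
            write_tsv(scores, out_dir / "pca_scores.tsv")
            pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(frac))],
                          "variance_pct": frac}).to_csv(
                out_dir / "pca_variance.tsv", sep="\t", index=False)
            outputs["pca_variance_pct"] = [float(f) for f in frac[:2]]

    # --- truth comparison (simulation runs only) ---------------------------
    truth_metrics = None
    if "truth" in paths and Path(paths["truth"]).exists():
        truth = TruthTable.read_tsv(paths["truth"])
        truth_metrics = evaluate_against_truth(filter_log, diff, site_ids, truth)

    # --- manifest & report --------------------------------------------------
    manifest = {
        "package_version": __version__,
        "thresholds": asdict(thresholds),
        "filter_config": _jsonable(asdict(filter_config)),
        "test_config": asdict(test_config),
        "sim_config": _jsonable(asdict(sim_config)) if sim_config else None,
        "n_calls": len(calls),
        "n_candidates": len(candidates),
        "n_accepted": len(accepted),
        "n_dre": int(diff["is_dre"].sum()) if len(diff) else 0,
        "truth_metrics": truth_metrics,
        "outputs": outputs,
        "files": {},
    }
    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name not in ("manifest.json", "report.md"):
            manifest["files"][str(p.relative_to(out_dir))] = _sha256(p)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _write_report(out_dir / "report.md", manifest)
    return manifest


def _jsonable(d):
    out = {}
    for k, v in d.items():
        if isinstance(v, (frozenset, set, tuple)):
            out[k] = sorted(v) if isinstance(v, (frozenset, set)) else list(v)
        else:
            out[k] = v
    return out


def _write_report(path: Path, manifest: dict) -> None:
    lines = ["# Pipeline report", "",
             f"- calls: {manifest['n_calls']}",
             f"- coding-strand A>G candidates: {manifest['n_candidates']}",
             f"- accepted editing sites: {manifest['n_accepted']}",
             f"- DRE sites: {manifest['n_dre']}", ""]
    tm = manifest.get("truth_metrics")
    if tm:
        lines += ["## Planted-truth recovery", ""]
        for k, v in sorted(tm.items()):
            lines.append(f"- {k}: {v}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# truth evaluation

def evaluate_against_truth(filter_log: pd.DataFrame, diff: pd.DataFrame,
                           site_ids: list[str], truth: TruthTable) -> dict:
    """Recovery metrics of a pipeline run against the simulator's truth."""
    accepted_pos = {site_ids[i] for i in range(len(site_ids))}
    log_by_pos = {}
    for _, row in filter_log.iterrows():
        log_by_pos[(row["chrom"], int(row["pos"]) - 1)] = row

    edit = truth.editing_records
    n_edit_ok = sum(1 for r in edit
                    if f"{r.chrom}:{r.pos + 1}" in accepted_pos)
    out = {
        "n_planted_editing": len(edit),
        "editing_recovery": n_edit_ok / len(edit) if edit else float("nan"),
    }
    for cls, reason in EXPECTED_REMOVAL_REASON.items():
        recs = truth.by_class(cls)
        if not recs:
            continue
        ok = 0
        for r in recs:
            row = log_by_pos.get((r.chrom, r.pos))
            if row is not None and row["status"] == "removed" \
                    and row["first_fail"] == reason:
                ok += 1
        out[f"removal_{cls}"] = ok / len(recs)

    dre_truth = {f"{r.chrom}:{r.pos + 1}" for r in truth.by_class("editing_dre")}
    if len(diff):
        flagged = set(diff.loc[diff["is_dre"], "site"])
        out["dre_sensitivity"] = (len(flagged & dre_truth) / len(dre_truth)
                                  if dre_truth else float("nan"))
        out["dre_fdp"] = (len(flagged - dre_truth) / len(flagged)
                          if flagged else 0.0)
    return out
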