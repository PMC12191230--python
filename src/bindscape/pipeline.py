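"""Pipeline arms tying the analysis stages together, with manifest output.

Two arms mirror the study design: a genomics arm (peak-set Jaccard, A/B/C
target partitioning, motif and flanking-base analysis) and an SMT arm
(fast-modality 3-state fitting plus per-cell features, slow-modality
survival fitting, IQR-based per-cell QC). Every run writes a manifest JSON
listing each artifact with its SHA-256 checksum and the full parameter set,
so outputs are reproducible byte-for-byte from (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import fastkinetics, motifs, peaks, qc, slowkinetics
from .intervals import PeakSet
from .trajectories import read_trajectory_csv

__all__ = ["run_genomics_arm", "run_smt_arm", "read_peak_fasta"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, params: dict, artifacts: list[Path]) -> Path:
    manifest = {
        "parameters": params,
        "artifacts": {
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(artifacts)
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def read_peak_fasta(path: str | Path) -> dict[str, str]:
    """Peak sequences keyed by FASTA record id (the BED name column)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_genomics_arm(
    out_dir: str | Path,
    wt_bed: str | Path,
    variant_bed: str | Path,
    peak_fasta: str | Path,
    gene_table: str | Path | None = None,
    min_overlap_bp: int = 1,
    flank_core: str = motifs.NKE_CORE,
    enrichment_motif: str | None = None,
    n_perm: int = 200,
    basal_up: int = 6500,
    basal_down: int = 2500,
    max_ext: int = 100000,
    seed: int = 0,
) -> dict:
    """Jaccard, A/B/C partition, gene assignment and motif tables for one pair."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in (wt_bed, variant_bed, peak_fasta):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    wt = PeakSet.from_bed(wt_bed, allele="WT", merge=False)
    var = PeakSet.from_bed(variant_bed, allele="variant", merge=False)
    sequences = read_peak_fasta(peak_fasta)

    artifacts: list[Path] = []
    jm = peaks.jaccard_matrix([wt, var])
    jm.to_csv(out / "jaccard.csv")
    artifacts.append(out / "jaccard.csv")

    part = peaks.classify_targets(wt, var, min_overlap_bp=min_overlap_bp)
    if gene_table is not None:
        genes = peaks.read_gene_table(gene_table)
        assignment = peaks.assign_genes(
            PeakSet("all", list(wt) + list(var)),
            genes, basal_up, basal_down, max_ext,
        )
        peaks.partition_gene_sets(part, assignment)
    for label, ps in (("a", part.a_peaks), ("b", part.b_peaks), ("c", part.c_peaks)):
        ps.to_bed(out / f"{label}_peaks.bed")
        artifacts.append(out / f"{label}_peaks.bed")
    summary = part.summary()
    summary["jaccard_wt_variant"] = float(jm.values[0, 1])
    summary["a_genes"] = sorted(part.a_genes)
    summary["b_genes"] = sorted(part.b_genes)
    summary["c_genes"] = sorted(part.c_genes)
    with open(out / "partition.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    artifacts.append(out / "partition.json")

    wt_seqs = [sequences[iv.name] for iv in wt if iv.name in sequences]
    try:
        flank = motifs.flank_preference(wt_seqs, core=flank_core)
        flank.counts.rename_axis("base").to_csv(out / "flank_preference.csv")
        artifacts.append(out / "flank_preference.csv")
    except ValueError:
        pass  # core absent from every sequence: no flank table

    if enrichment_motif is not None:
        z = motifs.enrichment_z(
            None, wt_seqs, enrichment_motif, n_perm=n_perm, seed=seed
        )
        pd.DataFrame(
            [{"motif": enrichment_motif, "z": z, "n_perm": n_perm, "seed": seed}]
        ).to_csv(out / "enrichment_z.csv", index=False)
        artifacts.append(out / "enrichment_z.csv")

    params = {
        "arm": "genomics",
        "wt_bed": str(wt_bed),
        "variant_bed": str(variant_bed),
        "peak_fasta": str(peak_fasta),
        "gene_table": str(gene_table) if gene_table else None,
        "min_overlap_bp": min_overlap_bp,
        "flank_core": flank_core,
        "enrichment_motif": enrichment_motif,
        "n_perm": n_perm,
        "basal_up": basal_up,
        "basal_down": basal_down,
        "max_ext": max_ext,
        "seed": seed,
    }
    _write_manifest(out, params, artifacts)
    summary["manifest"] = str(out / "manifest.json")
    return summary


def run_smt_arm(
    out_dir: str | Path,
    fast_csvs: Sequence[str | Path] = (),
    slow_csvs: Sequence[str | Path] = (),
    fast_interval: float = 0.020,
    slow_interval: float = 0.500,
    pixel_size: float = 0.1,
    n_lags: int = 6,
    n_init: int = 10,
    iqr_k: float = 1.5,
    d_threshold: float = 0.1,
    seed: int = 0,
) -> dict:
    """Fast (3-state fit, per-cell features) and slow (survival fit) sub-pipelines.

    Each CSV is one cell. Cells whose median per-track D is an IQR outlier
    across cells are removed before pooled fitting. Returns a summary dict;
    artifacts and a checksum manifest are written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    summary: dict = {"arm": "smt", "fast": None, "slow": None}

    if fast_csvs:
        cells = {
            Path(p).stem: read_trajectory_csv(p, fast_interval, pixel_size)
            for p in fast_csvs
        }
        summaries = [
            fastkinetics.cell_features(trajs, cell_id=cid, d_threshold=d_threshold)
            for cid, trajs in cells.items()
        ]
        med_d = [s.feature_vector()["median_track_d"] for s in summaries]
        keep = (
            qc.iqr_filter(med_d, k=iqr_k)
            if len(summaries) >= 4
            else np.ones(len(summaries), dtype=bool)
        )
        kept = [s for s, k in zip(summaries, keep) if k]
        kept_ids = {s.cell_id for s in kept}
        pooled = [t for cid, trajs in cells.items() if cid in kept_ids for t in trajs]
        rows = [dict(cell_id=s.cell_id, kept=bool(k), **s.feature_vector())
                for s, k in zip(summaries, keep)]
        pd.DataFrame(rows).to_csv(out / "cell_features.csv", index=False)
        artifacts.append(out / "cell_features.csv")
        if pooled:
            fit = fastkinetics.fit_three_state(
                pooled, n_lags=n_lags, n_init=n_init, seed=seed
            )
            with open(out / "three_state_fit.json", "w") as fh:
                json.dump(fit.to_dict(), fh, indent=2)
            artifacts.append(out / "three_state_fit.json")
            summary["fast"] = {
                "n_cells": len(summaries),
                "n_cells_kept": int(keep.sum()),
                "n_tracks": len(pooled),
                "fit": fit.to_dict(),
            }
        else:
            summary["fast"] = {"n_cells": len(summaries), "n_cells_kept": 0,
                               "n_tracks": 0, "fit": None}

    if slow_csvs:
        durations = []
        for p in slow_csvs:
            trajs = read_trajectory_csv(p, slow_interval, pixel_size)
            durations.append(slowkinetics.residence_times(trajs))
        durations = np.concatenate(durations) if durations else np.empty(0)
        if len(durations) >= 10:
            curve = slowkinetics.survival_curve(durations)
            pd.DataFrame(curve, columns=["t_s", "survival"]).to_csv(
                out / "survival_curve.csv", index=False
            )
            artifacts.append(out / "survival_curve.csv")
            fits = {
                "1-exp": slowkinetics.fit_exponentials(curve, 1, seed=seed).to_dict(),
                "2-exp": slowkinetics.fit_exponentials(curve, 2, seed=seed).to_dict(),
            }
            with open(out / "survival_fits.json", "w") as fh:
                json.dump(fits, fh, indent=2)
            artifacts.append(out / "survival_fits.json")
            summary["slow"] = {"n_durations": int(len(durations)), "fits": fits}
        else:
            summary["slow"] = {"n_durations": int(len(durations)), "fits": None}

    params = {
        "fast_csvs": [str(p) for p in fast_csvs],
        "slow_csvs": [str(p) for p in slow_csvs],
        "fast_interval": fast_interval,
        "slow_interval": slow_interval,
        "pixel_size": pixel_size,
        "n_lags": n_lags,
        "n_init": n_init,
        "iqr_k": iqr_k,
        "d_threshold": d_threshold,
        "seed": seed,
    }
    _write_manifest(out, params, artifacts)
    summary["manifest"] = str(out / "manifest.json")
    return summary
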