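"""End-to-end triage: ranked screen → enrichment → gates → MD stability report.

The pipeline composes the independently invokable stages in the order a
repurposing screen uses them: rank the docking-score table, compute the
enrichment factor from labeled actives, apply the candidate-selection gates,
then summarize per-compound MD replicate RMSD series into the censored
window-median ranking. Every output is a plain TSV/CSV written from the
inputs and configuration alone, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .errors import DockTriageError
from .stability import compound_stability, rank_ligands
from .struct_io import read_rmsd_series
from .triage import enrichment_factor, rank_compounds, select_candidates

__all__ = ["run_pipeline"]

log = logging.getLogger("docktriage")


def _read_manifest(path: Path) -> list[tuple[str, list[Path]]]:
    """Manifest TSV: compound id followed by its replicate series paths."""
    entries = []
    base = path.parent
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise DockTriageError(f"{path}:{lineno}: manifest rows need a compound and ≥1 path")
        entries.append((parts[0], [base / p for p in parts[1:]]))
    return entries


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every configured stage; returns the paths of the written reports."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if config.screen.table is not None:
        table_path = Path(config.screen.table)
        if not table_path.exists():
            raise DockTriageError(f"screen stage: table not found: {table_path}")
        log.info("screen stage: reading %s", table_path)
        table = pd.read_csv(table_path, sep="\t")
        ranked = rank_compounds(table, lower_is_better=config.screen.lower_is_better)
        ranked_path = out_dir / "ranked.tsv"
        ranked.to_csv(ranked_path, sep="\t", index=False, float_format="%.6g")
        written["ranked"] = ranked_path

        if "active" in ranked.columns and ranked["active"].astype(bool).any():
            ef = enrichment_factor(ranked, config.screen.fraction)
            ef_path = out_dir / "enrichment.txt"
            ef_path.write_text(
                "\n".join(
                    [
                        f"fraction: {ef.fraction}",
                        f"n_total: {ef.n_total}",
                        f"n_top: {ef.n_top}",
                        f"n_actives: {ef.n_actives}",
                        f"n_actives_in_bin: {ef.n_actives_in_bin}",
                        f"ef: {ef.ef:.4f}",
                    ]
                )
                + "\n"
            )
            written["enrichment"] = ef_path
            log.info("screen stage: EF_%.0f%% = %.2f", 100 * ef.fraction, ef.ef)
        else:
            log.info("screen stage: no active labels; skipping enrichment factor")

        thresholds = config.screen.thresholds()
        candidates, trail = select_candidates(
            ranked, thresholds, lower_is_better=config.screen.lower_is_better
        )
        cand_path = out_dir / "candidates.tsv"
        candidates.to_csv(cand_path, sep="\t", index=False, float_format="%.6g")
        trail_path = out_dir / "decisions.tsv"
        trail.to_csv(trail_path, sep="\t", index=False)
        written["candidates"] = cand_path
        written["decisions"] = trail_path
        log.info("screen stage: %d/%d candidates pass the gates", len(candidates), len(ranked))

    if config.stability.manifest is not None:
        manifest_path = Path(config.stability.manifest)
        if not manifest_path.exists():
            raise DockTriageError(f"stability stage: manifest not found: {manifest_path}")
        cfg = config.stability.stability_config()
        results = []
        for compound, paths in _read_manifest(manifest_path):
            replicates = []
            for i, p in enumerate(paths, start=1):
                if not p.exists():
                    raise DockTriageError(f"stability stage: series file not found: {p}")
                replicates.append(
                    read_rmsd_series(p.read_text(), unit=config.stability.unit,
                                     replicate_id=f"{compound}-rep{i}")
                )
            result = compound_stability(compound, replicates, cfg)
            results.append(result)
            med_path = out_dir / f"median_{compound}.csv"
            pd.DataFrame(
                {"time_ns": result.median_series.times, "rmsd_A": result.median_series.values}
            ).to_csv(med_path, index=False, float_format="%.6g")
            written[f"median_{compound}"] = med_path
        summary = rank_ligands(results)
        stab_path = out_dir / "stability.tsv"
        summary.to_csv(stab_path, sep="\t", index=False, float_format="%.6g")
        written["stability"] = stab_path
        log.info("stability stage: %d compounds ranked", len(summary))

    cfg_path = out_dir / "config_used.yaml"
    cfg_path.write_text(config.dump())
    written["config"] = cfg_path
    return written
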