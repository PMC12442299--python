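"""End-to-end orchestration over a manifest of reference/isoform pairs.

Applies the cohort quality filters (sequence length, mean pLDDT, optional
strict non-IDR / non-isolated-helix subset), runs per-pair alignment, event
classification, structural metrics and PTM classification, then the
cohort-level stages: IQR outlier tables, per-residue-effect regressions and
a machine-readable run log. A stage failure isolates the pair and the run
continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import align as _align
from . import metrics as _metrics
from . import ptm as _ptm
from . import regression as _regression
from . import splice as _splice
from .io import ProteinStructure, PTMRecord, TranscriptModel, read_pdb

__all__ = ["RunConfig", "PairInput", "apply_filters", "run_pipeline"]

logger = logging.getLogger("isoformetrics")


@dataclass
class RunConfig:
    """All thresholds and knobs of one pipeline run."""

    rsa_threshold: float = 0.25
    idr_window: int = 25
    idr_cutoff: float = 70.0
    idr_min_len: int = 20
    helix_min_run: int = 21
    confidence_threshold: float = 0.6
    min_cells: int = 30
    max_length: int = 600          # sequences must be shorter than this
    min_mean_plddt: float = 70.0   # structures at or below are dropped
    strict_subset: bool = False    # additionally drop IDR / isolated-helix structures
    open_gap: float = -10.0
    extend_gap: float = -0.5
    sasa_n_points: int = 960
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rsa_threshold <= 1:
            raise ValueError("rsa_threshold must lie in [0, 1]")
        if self.max_length < 1 or self.idr_window < 1 or self.idr_min_len < 1:
            raise ValueError("length/window thresholds must be positive")
        if not 0 <= self.min_mean_plddt <= 100:
            raise ValueError("min_mean_plddt must lie in [0, 100]")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PairInput:
    """One manifest row: a reference/isoform pair and its optional extras."""

    gene_id: str
    ref_id: str
    iso_id: str
    ref_structure: ProteinStructure | str | Path
    iso_structure: ProteinStructure | str | Path
    ref_transcript: TranscriptModel | None = None
    iso_transcript: TranscriptModel | None = None
    ptm_sites: list[PTMRecord] = field(default_factory=list)

    def load(self) -> tuple[ProteinStructure, ProteinStructure]:
        ref = self.ref_structure
        iso = self.iso_structure
        if not isinstance(ref, ProteinStructure):
            ref = read_pdb(ref, id=self.ref_id)
        if not isinstance(iso, ProteinStructure):
            iso = read_pdb(iso, id=self.iso_id)
        return ref, iso


def _passes(structure: ProteinStructure, config: RunConfig, log: list[dict],
            pair_id: str) -> bool:
    reasons = []
    if len(structure) >= config.max_length:
        reasons.append(f"length {len(structure)} >= {config.max_length}")
    if _metrics.mean_plddt(structure) <= config.min_mean_plddt:
        reasons.append(f"mean pLDDT {_metrics.mean_plddt(structure):.1f} <= "
                       f"{config.min_mean_plddt}")
    if config.strict_subset and not reasons:
        if _metrics.idr_regions(structure, config.idr_window, config.idr_cutoff,
                                config.idr_min_len):
            reasons.append("contains IDR (strict subset)")
        else:
            sasa = _metrics.shrake_rupley_sasa(structure, n_points=config.sasa_n_points)
            if _metrics.isolated_helices(structure, sasa, min_run=config.helix_min_run,
                                         rsa_threshold=config.rsa_threshold):
                reasons.append("contains isolated helix (strict subset)")
    for r in reasons:
        log.append({"pair": pair_id, "structure": structure.id, "dropped": r})
    return not reasons


def apply_filters(pairs: list[PairInput], config: RunConfig) -> tuple[list[PairInput], list[dict]]:
    """Keep pairs where BOTH members pass the quality filters."""
    kept = []
    log: list[dict] = []
    for pair in pairs:
        try:
            ref, iso = pair.load()
        except Exception as exc:  # missing/corrupt file isolates the pair
            log.append({"pair": pair.iso_id, "structure": None, "dropped": str(exc)})
            continue
        ok_ref = _passes(ref, config, log, pair.iso_id)
        ok_iso = _passes(iso, config, log, pair.iso_id)
        if ok_ref and ok_iso:
            pair = dataclasses.replace(pair, ref_structure=ref, iso_structure=iso)
            kept.append(pair)
    return kept, log


def run_pipeline(pairs: list[PairInput], config: RunConfig | None = None) -> dict:
    """Run all per-pair and cohort-level stages; returns a report bundle.

    The bundle maps table names to DataFrames: ``pairs`` (per-pair metrics and
    differences), ``events``, ``alignments``, ``ptm``, ``outliers``,
    ``effects`` (when enough pairs for a full-rank design), and ``log``.
    """
    config = config or RunConfig()
    kept, filter_log = apply_filters(pairs, config)

    pair_rows = []
    event_rows = []
    aln_rows = []
    ptm_rows = []
    pair_reports: list[_metrics.PairReport] = []
    event_sets: dict[str, _splice.SpliceEventSet] = {}
    run_log = list(filter_log)

    for pair in kept:
        try:
            ref, iso = pair.load()
            aln = _align.global_align(ref.sequence, iso.sequence,
                                      ref_id=pair.ref_id, iso_id=pair.iso_id,
                                      open_gap=config.open_gap,
                                      extend_gap=config.extend_gap)
            identity = _align.sequence_identity(aln)
            ref_rep = _metrics.compute_metrics(
                ref, rsa_threshold=config.rsa_threshold, idr_window=config.idr_window,
                idr_cutoff=config.idr_cutoff, idr_min_len=config.idr_min_len,
                helix_min_run=config.helix_min_run, sasa_n_points=config.sasa_n_points)
            iso_rep = _metrics.compute_metrics(
                iso, rsa_threshold=config.rsa_threshold, idr_window=config.idr_window,
                idr_cutoff=config.idr_cutoff, idr_min_len=config.idr_min_len,
                helix_min_run=config.helix_min_run, sasa_n_points=config.sasa_n_points)
            tm = _metrics.tm_score(ref, iso, aln)
            pr = _metrics.pair_report(ref_rep, iso_rep, tm)
            pair_reports.append(pr)
            pair_rows.append({
                "gene_id": pair.gene_id, "ref_id": pair.ref_id, "iso_id": pair.iso_id,
                "identity": identity, "tm": tm,
                "ref_len": len(ref), "iso_len": len(iso),
                "ref_mean_plddt": ref_rep.mean_plddt, "iso_mean_plddt": iso_rep.mean_plddt,
                "d_helix": pr.d_helix, "d_sheet": pr.d_sheet, "d_loop": pr.d_loop,
                "d_charge": pr.d_charge, "d_rg": pr.d_rg, "d_idr": pr.d_idr,
                "d_plddt": pr.d_plddt,
            })
            aln_rows.extend(
                {"ref_id": pair.ref_id, "iso_id": pair.iso_id,
                 "ref_pos": r if r is not None else "-",
                 "iso_pos": i if i is not None else "-", "label": lab}
                for (r, i), lab in zip(aln.columns, _align.label_regions(aln).labels)
            )
            if pair.ref_transcript is not None and pair.iso_transcript is not None:
                events = _splice.compare_exon_chains(pair.ref_transcript, pair.iso_transcript)
                event_sets[pair.iso_id] = events
                for ev in events.events:
                    event_rows.append({
                        "ref_id": pair.ref_id, "iso_id": pair.iso_id, "type": ev.type,
                        "host": ev.host, "delta_nt": ev.delta_nt,
                    })
            if pair.ptm_sites:
                ref_sasa = _metrics.shrake_rupley_sasa(ref, n_points=config.sasa_n_points)
                iso_sasa = _metrics.shrake_rupley_sasa(iso, n_points=config.sasa_n_points)
                for site in pair.ptm_sites:
                    cl = _ptm.classify_ptm(site, ref, iso, aln,
                                           rsa_threshold=config.rsa_threshold,
                                           ref_sasa=ref_sasa, iso_sasa=iso_sasa)
                    ptm_rows.append({
                        "protein_id": site.protein_id, "position": site.position,
                        "ptm_type": site.ptm_type, "category": cl.category,
                        "ref_rsa": cl.ref_rsa, "iso_rsa": cl.iso_rsa,
                        "flags": ";".join(cl.flags),
                    })
        except Exception as exc:
            logger.warning("pair %s failed: %s", pair.iso_id, exc)
            run_log.append({"pair": pair.iso_id, "structure": None,
                            "dropped": f"stage failure: {exc}"})

    pairs_df = pd.DataFrame(pair_rows)
    bundle: dict = {
        "pairs": pairs_df,
        "events": pd.DataFrame(event_rows),
        "alignments": pd.DataFrame(aln_rows),
        "ptm": pd.DataFrame(ptm_rows),
        "log": pd.DataFrame(run_log),
        "run": {"config_hash": config.hash(), "seed": config.seed,
                "n_input_pairs": len(pairs), "n_analyzed": len(pair_rows)},
    }

    # cohort outliers on the signed metric differences
    outlier_rows = []
    if len(pairs_df):
        for metric in ("d_charge", "d_rg"):
            labels = _metrics.classify_outliers(pairs_df[metric].to_numpy())
            for iso_id, lab, v in zip(pairs_df["iso_id"], labels, pairs_df[metric]):
                outlier_rows.append({"iso_id": iso_id, "metric": metric,
                                     "value": v, "label": lab})
    bundle["outliers"] = pd.DataFrame(outlier_rows)

    # per-residue-effect regressions where the design is estimable
    if event_sets and len(pair_reports) > len(_splice.SIGNED_FEATURES) + 2:
        usable = [pr for pr in pair_reports if pr.iso_id in event_sets]
        tables = {}
        for outcome in _regression.OUTCOME_METRICS:
            try:
                design = _regression.build_design(usable, event_sets, outcome)
                tables[outcome] = _regression.fit_ols(design)
            except ValueError as exc:
                run_log.append({"pair": None, "structure": None,
                                "dropped": f"regression {outcome}: {exc}"})
        if tables:
            bundle["effects"] = _regression.effect_summary(tables)
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write every table of a report bundle as TSV plus the JSON run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        else:
            (out / f"{name}.json").write_text(json.dumps(obj, indent=2, sort_keys=True))
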