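"""Orchestration: per-marker and combined multi-marker analyses.

`run_marker` executes the full distance-based delimitation chain on one
aligned marker — site statistics, optional coding screen, haplotype
collapsing, K2P distances, barcoding gap and 4x tests, statistical-parsimony
networks, depth-break scan, and (when a tree is available) the single-
threshold GMYC test. `run_combined` concatenates markers, collapses to unique
concatenated haplotypes, reruns the distance-based stages, and reports
cross-marker partition congruence. Reports are plain nested dicts with a
provenance block, exportable as JSON, TSV tables, and a text summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import delimit, distances, gmyc, haplotypes, parsnet, seqio

__all__ = ["PipelineConfig", "run_marker", "run_combined", "write_reports"]


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters, echoed verbatim into every report."""

    distance_model: str = "K2P"
    on_saturation: str = "error"
    gap_mode: str = "fifth_state"
    parsimony_threshold: float = 0.95
    fixed_limit: int | None = None
    depth_cut: float = 3000.0
    coding_markers: tuple[str, ...] = ("COI",)
    code_table: int = 5
    build_upgma_tree: bool = False
    lrt_df: int = 3

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["coding_markers"] = list(self.coding_markers)
        return d


def _check_ids(aln: seqio.Alignment, metadata: seqio.SpecimenTable):
    orphans = [i for i in aln.ids if i not in metadata.df.index]
    if orphans:
        raise ValueError(f"sequence ids missing from metadata: {orphans}")


def _clade_table_rows(summary: distances.CladeDivergenceTable) -> list[dict]:
    rows = []
    for r in summary.rows:
        rows.append(
            {
                "clade": r["clade"],
                "n_members": r["n_members"],
                "intra_min": r["intra"]["min"] if r["intra"] else None,
                "intra_max": r["intra"]["max"] if r["intra"] else None,
                "intra_mean": r["intra"]["mean"] if r["intra"] else None,
                "inter_min": r["inter"]["min"] if r["inter"] else None,
                "inter_max": r["inter"]["max"] if r["inter"] else None,
                "inter_mean": r["inter"]["mean"] if r["inter"] else None,
            }
        )
    return rows


def run_marker(
    aln: seqio.Alignment,
    metadata: seqio.SpecimenTable,
    partition: delimit.Partition | None = None,
    tree: gmyc.UltrametricTree | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run every applicable stage on one marker; see module docstring.

    Without a supplied partition, one is proposed by single-linkage clustering
    at the midpoint of the widest gap in the pairwise-distance distribution
    and labelled ``proposed``. Stages whose inputs are unavailable are
    reported as skipped with the reason.
    """
    _check_ids(aln, metadata)
    caught: list[str] = []
    report: dict = {
        "marker": aln.marker,
        "n_sequences": len(aln),
        "n_columns": aln.n_columns,
        "provenance": {"config": config.to_dict()},
        "warnings": caught,
    }
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        sc = seqio.count_site_classes(aln)
        report["site_classes"] = dict(sc.__dict__)

        if aln.marker in config.coding_markers:
            pg = seqio.check_coding(aln, code_table=config.code_table)
            report["coding_screen"] = {
                "frame": pg.frame,
                "code_table": pg.code_table,
                "any_internal_stop": pg.any_internal_stop,
                "n_flagged": sum(r["has_internal_stop"] for r in pg.rows),
            }
        else:
            report["coding_screen"] = {"skipped": "marker not protein-coding"}

        haps = haplotypes.collapse(aln, metadata)
        haps = haplotypes.expand_multiplicities(haps, metadata)
        report["haplotypes"] = {
            "n_haplotypes": len(haps),
            "total_multiplicity": haps.total_multiplicity,
            "shared_between_basins": haplotypes.shared_haplotypes(
                haps, metadata, group_by="basin"
            ),
        }

        dm = distances.distance_matrix(
            aln, model=config.distance_model, on_saturation=config.on_saturation
        )
        if partition is None:
            threshold = delimit.detect_distance_gap(dm)
            if threshold is not None:
                partition = delimit.threshold_clusters(dm, threshold)
                report["partition"] = {
                    "origin": "proposed",
                    "threshold": threshold,
                    "n_clades": len(partition.clades),
                }
            else:
                report["partition"] = {"skipped": "no distance structure to propose clades"}
        else:
            report["partition"] = {
                "origin": "supplied",
                "n_clades": len(partition.clades),
            }
        if partition is not None:
            report["partition"]["assignment"] = partition.mapping
            summary = distances.intra_inter_summary(dm, partition)
            report["clade_divergences"] = _clade_table_rows(summary)
            gap = delimit.barcoding_gap(dm, partition) if len(partition.clades) >= 2 else None
            report["barcoding_gap"] = (
                {
                    "status": gap.status,
                    "max_intra": gap.max_intra,
                    "min_inter": gap.min_inter,
                }
                if gap
                else {"skipped": "single clade"}
            )
            fx = delimit.four_x(dm, partition) if len(partition.clades) >= 2 else None
            report["four_x"] = (
                {"global_pass": fx.global_pass, "pairs": [dict(p) for p in fx.pairs]}
                if fx
                else {"skipped": "single clade"}
            )
            report["depth_break"] = _depth_break_section(partition, metadata)

        limit = parsnet.connection_limit(
            aln.n_columns,
            threshold=config.parsimony_threshold,
            fixed_limit=config.fixed_limit,
        )
        nets = parsnet.build_networks(haps, limit, gap_mode=config.gap_mode)
        report["networks"] = {
            "connection_limit": limit.j_max,
            "n_networks": len(nets),
            "n_singletons": sum(1 for n in nets if n.is_singleton),
            "summary": parsnet.network_summary(
                nets, haps, metadata, depth_cut=config.depth_cut
            ),
        }

        if tree is None and config.build_upgma_tree:
            tree = gmyc.upgma(dm)
            report.setdefault("provenance", {})["tree"] = "UPGMA from distance matrix"
        if tree is None:
            report["gmyc"] = {"skipped": "no tree"}
        elif tree.n_tips < 4:
            report["gmyc"] = {"skipped": "tree too small for GMYC"}
        else:
            null = gmyc.fit_null(tree)
            fit = gmyc.fit_gmyc_single(tree)
            test = gmyc.lrt(null, fit, df=config.lrt_df)
            report["gmyc"] = {
                "null_lnL": null.lnL,
                "gmyc_lnL": fit.lnL,
                "threshold": fit.threshold,
                "n_clusters": fit.n_clusters,
                "n_entities": fit.n_entities,
                "lrt_statistic": test.statistic,
                "p_value": test.p_value,
                "df": test.df,
            }
        caught.extend(str(w.message) for w in wlist)
    return report


def _depth_break_section(partition, metadata) -> dict:
    db = delimit.depth_break(partition, metadata)
    return {
        "status": db.status,
        "interval": list(db.interval) if db.interval else None,
        "clade_depth_ranges": {c: list(r) for c, r in db.clade_depth_ranges.items()},
    }


def run_combined(
    alignments: list[seqio.Alignment],
    metadata: seqio.SpecimenTable,
    partitions: dict | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Concatenate markers, analyse the combined data, compare partitions.

    ``partitions`` optionally maps marker name to a per-marker
    :class:`~eurydelim.delimit.Partition`; pairwise congruence between them is
    reported. The combined stages use unique concatenated haplotypes, as a
    multi-locus analysis would.
    """
    if len(alignments) < 2:
        raise ValueError("combined analysis requires >= 2 markers")
    concat = seqio.concatenate(alignments, join_policy="drop")
    aln = concat.alignment
    _check_ids(aln, metadata)
    report: dict = {
        "markers": [a.marker for a in alignments],
        "n_specimens": len(aln),
        "n_columns": aln.n_columns,
        "blocks": [list(b) for b in concat.blocks],
        "provenance": {"config": config.to_dict()},
    }
    haps = haplotypes.collapse(aln, metadata)
    report["n_unique_concatenated"] = len(haps)
    rep_aln = haps.to_alignment()
    dm = distances.distance_matrix(
        rep_aln, model=config.distance_model, on_saturation=config.on_saturation
    )
    threshold = delimit.detect_distance_gap(dm)
    if threshold is not None:
        part = delimit.threshold_clusters(dm, threshold)
        report["partition"] = {
            "origin": "proposed",
            "threshold": threshold,
            "n_clades": len(part.clades),
        }
        if len(part.clades) >= 2:
            gap = delimit.barcoding_gap(dm, part)
            fx = delimit.four_x(dm, part)
            report["barcoding_gap"] = {
                "status": gap.status,
                "max_intra": gap.max_intra,
                "min_inter": gap.min_inter,
            }
            report["four_x"] = {"global_pass": fx.global_pass}
    congruence = {}
    if partitions:
        names = sorted(partitions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                congruence[f"{a} vs {b}"] = {
                    k: v
                    for k, v in delimit.compare_partitions(
                        partitions[a], partitions[b]
                    ).items()
                    if k in ("relation", "n_shared")
                }
    report["congruence"] = congruence
    return report


def write_reports(report: dict, outdir, formats=("json", "tsv", "txt")) -> list[Path]:
    """Write a report as JSON, Table-2-style TSV, and a text summary.

    Output order is deterministic; empty sections are omitted from the TSV
    and text renderings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = report.get("marker") or "+".join(report.get("markers", ["report"]))
    written = []
    if "json" in formats:
        p = outdir / f"{stem}.report.json"
        with open(p, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=str)
        written.append(p)
    if "tsv" in formats and report.get("clade_divergences"):
        p = outdir / f"{stem}.clade_divergences.tsv"
        pd.DataFrame(
            report["clade_divergences"],
            columns=[
                "clade", "n_members", "intra_min", "intra_max", "intra_mean",
                "inter_min", "inter_max", "inter_mean",
            ],
        ).to_csv(p, sep="\t", index=False, float_format="%.6f")
        written.append(p)
    if "txt" in formats:
        p = outdir / f"{stem}.summary.txt"
        p.write_text(_text_summary(report))
        written.append(p)
    return written


def _text_summary(report: dict) -> str:
    lines = []
    if "marker" in report:
        lines.append(f"Marker {report['marker']}: {report['n_sequences']} sequences, "
                     f"{report['n_columns']} columns")
    else:
        lines.append(f"Combined {'+'.join(report['markers'])}: "
                     f"{report['n_specimens']} specimens, {report['n_columns']} columns")
    sc = report.get("site_classes")
    if sc:
        lines.append(f"  sites: {sc['n_variable']} variable, "
                     f"{sc['n_parsimony_informative']} parsimony-informative")
    if report.get("haplotypes"):
        lines.append(f"  haplotypes: {report['haplotypes']['n_haplotypes']}")
    if "n_unique_concatenated" in report:
        lines.append(f"  unique concatenated sequences: {report['n_unique_concatenated']}")
    gap = report.get("barcoding_gap")
    if gap and "status" in gap:
        lines.append(f"  barcoding gap: {gap['status']} "
                     f"(max intra {gap['max_intra']}, min inter {gap['min_inter']})")
    fx = report.get("four_x")
    if fx and "global_pass" in fx:
        lines.append(f"  4x criterion: {'PASS' if fx['global_pass'] else 'FAIL'}")
    nets = report.get("networks")
    if nets:
        lines.append(f"  parsimony networks: {nets['n_networks']} "
                     f"(limit {nets['connection_limit']} steps)")
    db = report.get("depth_break")
    if db:
        lines.append(f"  depth break: {db['status']} {db.get('interval')}")
    g = report.get("gmyc")
    if g and "n_entities" in g:
        lines.append(f"  GMYC: {g['n_entities']} entities "
                     f"(LRT {g['lrt_statistic']:.3f}, p={g['p_value']:.4g})")
    for w in report.get("warnings", []):
        lines.append(f"  warning: {w}")
    return "\n".join(lines) + "\n"
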