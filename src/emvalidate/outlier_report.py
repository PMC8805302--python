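"""Aggregation of per-metric outliers into a spatially clustered to-do list.

Residues flagged by any metric are clustered by single-linkage connectivity
of their CA atoms at a 7 Å link distance; clusters are ranked by size so the
largest problem region tops the list, and residues belonging to no cluster
are pooled into a final "unclustered" row.  The full run is serialized into
a JSON report plus a plain-text viewer script for molecular-graphics tools.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model_checks import BFactorSummary, Clash
from .model_io import AtomicModel, ResidueKey, ca_coordinates

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierRecord",
    "OutlierCluster",
    "ValidationReport",
    "collect_outliers",
    "cluster_outliers",
    "build_report",
    "write_viewer_script",
    "file_sha256",
]


@dataclass(frozen=True)
class OutlierRecord:
    residue: ResidueKey
    metric: str  # smoc_z | fdr_backbone | clash | external
    value: float


@dataclass
class OutlierCluster:
    members: list[OutlierRecord]
    size: int  # distinct residues
    rank: int
    is_unclustered: bool = False

    def residues(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for rec in self.members:
            seen.setdefault(rec.residue, None)
        return list(seen)


def collect_outliers(series_list, clashes: list[Clash] | None = None) -> list[OutlierRecord]:
    """One record per (residue, metric) flagged by its own rule, in
    deterministic order (series order, then residue order)."""
    records: list[OutlierRecord] = []
    for series in series_list:
        for key in series.values:
            if series.outlier_flags.get(key):
                records.append(OutlierRecord(key, series.metric_name, series.values[key]))
    if clashes:
        worst: dict[ResidueKey, float] = {}
        for clash in clashes:
            for key, _name in (clash.atom_a, clash.atom_b):
                worst[key] = max(worst.get(key, 0.0), clash.overlap)
        for key, overlap in worst.items():
            records.append(OutlierRecord(key, "clash", overlap))
    return records


def cluster_outliers(
    records: list[OutlierRecord],
    model: AtomicModel,
    link_distance: float = 7.0,
) -> list[OutlierCluster]:
    """Single-linkage clusters of flagged residues by CA–CA distance.

    Components of two or more residues are ranked by descending size (ties
    broken by the first member's residue order); singletons and residues
    lacking a CA/P coordinate are pooled into a final unclustered group.
    """
    order: dict[ResidueKey, int] = {}
    by_residue: dict[ResidueKey, list[OutlierRecord]] = {}
    for rec in records:
        order.setdefault(rec.residue, len(order))
        by_residue.setdefault(rec.residue, []).append(rec)
    if not order:
        return []

    coords_map = ca_coordinates(model)
    keys = list(order)
    placed = [k for k in keys if k in coords_map]
    floating = [k for k in keys if k not in coords_map]
    for k in floating:
        logger.warning("outlier residue %s lacks CA/P; left unclustered", k.label())

    components: list[list[ResidueKey]] = []
    if placed:
        coords = np.array([coords_map[k] for k in placed])
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=link_distance, output_type="ndarray")
        n = len(placed)
        if len(pairs):
            data = np.ones(len(pairs))
            adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        else:
            adj = csr_matrix((n, n))
        n_comp, labels = connected_components(adj, directed=False)
        for c in range(n_comp):
            members = [placed[i] for i in np.flatnonzero(labels == c)]
            components.append(sorted(members, key=order.__getitem__))

    proper = [c for c in components if len(c) >= 2]
    proper.sort(key=lambda c: (-len(c), order[c[0]]))
    singles = sorted(
        [c[0] for c in components if len(c) == 1] + floating, key=order.__getitem__
    )

    clusters: list[OutlierCluster] = []
    for rank, comp in enumerate(proper, start=1):
        members = [rec for k in comp for rec in by_residue[k]]
        clusters.append(OutlierCluster(members=members, size=len(comp), rank=rank))
    if singles:
        members = [rec for k in singles for rec in by_residue[k]]
        clusters.append(
            OutlierCluster(
                members=members,
                size=len(singles),
                rank=len(proper) + 1,
                is_unclustered=True,
            )
        )
    return clusters


def _residue_dict(key: ResidueKey) -> dict:
    return {
        "chain_id": key.chain_id,
        "seq_num": key.seq_num,
        "insertion_code": key.insertion_code,
        "res_name": key.res_name,
    }


def _series_dict(series) -> dict:
    return {
        "metric": series.metric_name,
        "residues": [
            {
                **_residue_dict(k),
                "value": series.values[k],
                "outlier": bool(series.outlier_flags.get(k, False)),
            }
            for k in series.values
        ],
    }


@dataclass
class ValidationReport:
    """JSON-serializable summary of one validation run."""

    payload: dict

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls(payload=json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def build_report(
    global_scores=None,
    series_list=(),
    clusters=(),
    bfactor_summary: BFactorSummary | None = None,
    clashes: list[Clash] | None = None,
    clash_rate: float | None = None,
    provenance: dict | None = None,
) -> ValidationReport:
    """Assemble all computed results into one serializable report."""
    payload: dict = {"provenance": dict(provenance or {})}
    if global_scores is not None:
        payload["global_scores"] = {
            "fsc_avg": global_scores.fsc_avg,
            "ccc": global_scores.ccc,
            "mi": global_scores.mi,
            "ov": global_scores.ov,
            "contour_model": global_scores.contour_model.level,
            "contour_exp": global_scores.contour_exp.level,
        }
    payload["per_residue"] = [_series_dict(s) for s in series_list]
    payload["outlier_clusters"] = [
        {
            "rank": c.rank,
            "size": c.size,
            "unclustered": c.is_unclustered,
            "members": [
                {**_residue_dict(r.residue), "metric": r.metric, "value": r.value}
                for r in c.members
            ],
        }
        for c in clusters
    ]
    if bfactor_summary is not None:
        payload["bfactor"] = {
            "n_atoms": bfactor_summary.n_atoms,
            "mean": bfactor_summary.mean,
            "sd": bfactor_summary.sd,
            "min": bfactor_summary.min,
            "max": bfactor_summary.max,
            "peak_positions": bfactor_summary.peak_positions,
            "multimodal_warning": bfactor_summary.multimodal_warning,
            "unrefined_warning": bfactor_summary.unrefined_warning,
        }
    if clashes is not None:
        payload["clashes"] = {
            "note": "simplified vdW-overlap check, not a MolProbity clashscore",
            "rate_per_1000_atoms": clash_rate,
            "list": [
                {
                    "atom_a": {**_residue_dict(c.atom_a[0]), "atom": c.atom_a[1]},
                    "atom_b": {**_residue_dict(c.atom_b[0]), "atom": c.atom_b[1]},
                    "overlap": c.overlap,
                }
                for c in clashes
            ],
        }
    return ValidationReport(payload=payload)


def write_viewer_script(clusters: list[OutlierCluster], path) -> None:
    """Plain-text navigation list, one outlier per line, ordered by cluster rank.

    The format (chain, seq_num+icode, metric, value) is directly consumable by
    molecular-graphics scripting (e.g. a Coot go-to-residue loop).
    """
    lines = ["# outlier navigation list: cluster<TAB>chain<TAB>residue<TAB>metric<TAB>value"]
    for cluster in clusters:
        label = "unclustered" if cluster.is_unclustered else f"cluster_{cluster.rank}"
        for rec in cluster.members:
            resid = f"{rec.residue.seq_num}{rec.residue.insertion_code}"
            lines.append(
                f"{label}\t{rec.residue.chain_id}\t{resid}\t{rec.metric}\t{rec.value:.4f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
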