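"""Readers and writers for the standard text formats of the pipeline.

Expression matrices travel as gene x sample TSV or as MatrixMarket
triplet files with ``.rownames`` / ``.colnames`` sidecars; trees as
Newick or edge-list JSON; gene sets as GMT; clonotype tables as
AIRR-style TSV. All tables are UTF-8, tab-delimited, '.' decimal.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path
from typing import Dict, List, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import (
    CloneGenotype,
    CloneTree,
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    Repertoire,
    SampleMeta,
)
from .errors import ConfigError, FormatError, ParseError, TreeStructureError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a gene x sample expression matrix.

    ``tsv``: header row of sample ids, first column gene ids.
    ``mtx-triplet``: MatrixMarket file plus ``<path>.rownames`` and
    ``<path>.colnames`` sidecar files (one identifier per line).
    """
    path = Path(path)
    if format == "tsv":
        return _read_expression_tsv(path)
    if format == "mtx-triplet":
        return _read_expression_mtx(path)
    raise ConfigError(f"unknown expression format {format!r}")


def _read_expression_tsv(path: Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in frame.index]
    samples = [str(s) for s in frame.columns]
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric value {raw!r} at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
    return ExpressionMatrix(values, genes, samples)


def _read_expression_mtx(path: Path) -> ExpressionMatrix:
    rows_path = path.with_suffix(path.suffix + ".rownames")
    cols_path = path.with_suffix(path.suffix + ".colnames")
    for sidecar in (rows_path, cols_path):
        if not sidecar.exists():
            raise FormatError(f"missing sidecar name file {sidecar}")
    matrix = scipy.io.mmread(str(path))
    dense = np.asarray(
        matrix.todense() if scipy.sparse.issparse(matrix) else matrix, dtype=float
    )
    genes = rows_path.read_text().splitlines()
    samples = cols_path.read_text().splitlines()
    if dense.shape != (len(genes), len(samples)):
        raise FormatError(
            f"{path}: matrix shape {dense.shape} does not match sidecar names "
            f"({len(genes)} rows, {len(samples)} cols)"
        )
    return ExpressionMatrix(dense, genes, samples)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx-triplet":
        buffer = _io.BytesIO()
        scipy.io.mmwrite(buffer, scipy.sparse.coo_matrix(expr.values))
        path.write_bytes(buffer.getvalue())
        path.with_suffix(path.suffix + ".rownames").write_text(
            "\n".join(expr.gene_ids) + "\n"
        )
        path.with_suffix(path.suffix + ".colnames").write_text(
            "\n".join(expr.sample_ids) + "\n"
        )
    else:
        raise ConfigError(f"unknown expression format {format!r}")


def normalize_log2_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1) fallback normalizer.

    This is *not* a variance-stabilizing transformation; it is provided so
    raw count matrices can enter the pipeline without external tooling.
    """
    if np.any(counts.values < 0):
        raise FormatError("counts must be non-negative for CPM normalization")
    totals = counts.values.sum(axis=0)
    if np.any(totals <= 0):
        raise FormatError("every sample needs a positive library size")
    cpm = counts.values / totals * 1e6
    return ExpressionMatrix(np.log2(cpm + 1.0), counts.gene_ids, counts.sample_ids)


def filter_genes_by_tpm(
    tpm: ExpressionMatrix, min_tpm: float = 1.0, min_fraction: float = 0.20
) -> List[str]:
    """Genes detected at >= ``min_tpm`` in >= ``min_fraction`` of samples.

    Both thresholds are inclusive; input order is preserved.
    """
    if not (0.0 <= min_fraction <= 1.0):
        raise ConfigError(f"min_fraction must lie in [0, 1], got {min_fraction}")
    if np.any(tpm.values < 0):
        raise FormatError("TPM matrix must be non-negative")
    detected = (tpm.values >= min_tpm).sum(axis=1) / tpm.n_samples
    return [g for g, frac in zip(tpm.gene_ids, detected) if frac >= min_fraction]


# ---------------------------------------------------------------------------
# clone trees
# ---------------------------------------------------------------------------

def read_clone_tree(
    path: str | Path, format: str = "edge-json", patient_id: str | None = None
) -> CloneTree:
    path = Path(path)
    if format == "newick":
        return _read_tree_newick(path, patient_id or path.stem)
    if format == "edge-json":
        return _read_tree_json(path)
    raise ConfigError(f"unknown tree format {format!r}")


def _read_tree_newick(path: Path, patient_id: str) -> CloneTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    edges = []
    nodes = []
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if label is None:
            raise TreeStructureError(f"{path}: unlabelled clone node")
        node.clone_label = str(label)
        nodes.append(str(label))
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            edges.append((node.clone_label, child.clone_label))
    return CloneTree(patient_id, edges, nodes=nodes)


def _read_tree_json(path: Path) -> CloneTree:
    raw = json.loads(Path(path).read_text())
    genotypes = {}
    for clone, spec in (raw.get("genotypes") or {}).items():
        genotypes[clone] = CloneGenotype(
            clone_id=clone,
            driver_mutations=set(spec.get("driver_mutations", [])),
            cn={g: int(v) for g, v in spec.get("cn", {}).items()},
            arm_events=dict(spec.get("arm_events", {})),
        )
    return CloneTree(
        raw["patient_id"],
        [(e[0], e[1]) for e in raw.get("edges", [])],
        nodes=raw.get("nodes"),
        genotypes=genotypes,
    )


def write_clone_tree(tree: CloneTree, path: str | Path) -> None:
    payload = {
        "patient_id": tree.patient_id,
        "nodes": tree.nodes,
        "edges": [list(e) for e in tree.edges],
        "genotypes": {
            clone: {
                "driver_mutations": sorted(gt.driver_mutations),
                "cn": {g: int(v) for g, v in sorted(gt.cn.items())},
                "arm_events": dict(sorted(gt.arm_events.items())),
            }
            for clone, gt in sorted(tree.genotypes.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "sample_id",
    "patient_id",
    "sample_type",
    "purity",
    "wgii",
    "wgd",
    "driver_status",
    "clones",
]


def read_metadata(path: str | Path) -> List[SampleMeta]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    out = []
    for _, row in frame.iterrows():
        purity_raw = row["purity"]
        if purity_raw == "":
            logger.warning(
                "sample %s: missing purity, treating as 1.0", row["sample_id"]
            )
            purity = 1.0
        else:
            purity = float(purity_raw)
        drivers: Dict[str, bool] = {}
        if row["driver_status"]:
            for token in row["driver_status"].split(";"):
                name, _, flag = token.partition("=")
                drivers[name] = flag in ("1", "true", "True")
        clones = {c for c in row["clones"].split(";") if c}
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                sample_type=row["sample_type"],
                purity=purity,
                wgii=float(row["wgii"]) if row["wgii"] else 0.0,
                wgd=row["wgd"] in ("1", "true", "True"),
                driver_status=drivers,
                clones=clones,
            )
        )
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample ids")
    return out


def write_metadata(metadata: Sequence[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in metadata:
        rows.append(
            {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "sample_type": m.sample_type,
                "purity": repr(float(m.purity)),
                "wgii": repr(float(m.wgii)),
                "wgd": int(m.wgd),
                "driver_status": ";".join(
                    f"{k}={int(bool(v))}" for k, v in sorted(m.driver_status.items())
                ),
                "clones": ";".join(sorted(m.clones)),
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation, gene sets, copy number
# ---------------------------------------------------------------------------

def read_gene_annotations(path: str | Path) -> List[GeneAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "chromosome", "arm", "start", "end"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    return [
        GeneAnnotation(
            gene_id=row["gene_id"],
            chromosome=row["chromosome"],
            arm=row["arm"],
            start=int(row["start"]),
            end=int(row["end"]),
        )
        for _, row in frame.iterrows()
    ]


def write_gene_annotations(
    annotations: Sequence[GeneAnnotation], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "chromosome": a.chromosome,
                "arm": a.arm,
                "start": a.start,
                "end": a.end,
            }
            for a in annotations
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> List[GeneSet]:
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs name, desc, >=1 gene")
        sets.append(GeneSet(name=fields[0], gene_ids=set(fields[2:])))
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate gene set names")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "na"] + sorted(s.gene_ids)) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# repertoires (AIRR-style TSV)
# ---------------------------------------------------------------------------

_REP_COLUMNS = ["sample_id", "chain", "clonotype_key", "count"]


def read_repertoires(path: str | Path) -> List[Repertoire]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REP_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing clonotype columns {missing}")
    grouped: Dict[tuple, Dict[str, int]] = {}
    for _, row in frame.iterrows():
        key = (row["sample_id"], row["chain"])
        counts = grouped.setdefault(key, {})
        if row["clonotype_key"] in counts:
            raise FormatError(
                f"{path}: duplicate clonotype {row['clonotype_key']!r} "
                f"for sample {row['sample_id']}/{row['chain']}"
            )
        counts[row["clonotype_key"]] = int(row["count"])
    return [
        Repertoire(sample_id=sid, chain=chain, counts=counts)
        for (sid, chain), counts in sorted(grouped.items())
    ]


def write_repertoires(reps: Sequence[Repertoire], path: str | Path) -> None:
    rows = []
    for rep in sorted(reps, key=lambda r: (r.sample_id, r.chain)):
        for key, count in sorted(rep.counts.items()):
            rows.append(
                {
                    "sample_id": rep.sample_id,
                    "chain": rep.chain,
                    "clonotype_key": key,
                    "count": count,
                }
            )
    pd.DataFrame(rows, columns=_REP_COLUMNS).to_csv(path, sep="\t", index=False)
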