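"""Readers and writers for the package's tabular formats.

All tables are plain TSV with an optional block of ``#``-prefixed header
lines carrying version/seed/config metadata.  Genomic positions in TSVs are
1-based (converted to the internal 0-based convention on read); BED inputs
are natively 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    CandidateSnp,
    EqtlInstance,
    FounderExpression,
    StrainPanel,
    candidate_window,
)

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """Raised when an input table violates the documented format."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    dupes = df.columns[df.columns.duplicated()].tolist()
    if dupes:
        raise TableFormatError(f"{path}: duplicate column(s): {', '.join(dupes)}")


def _numeric_block(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    """Coerce columns to float, raising a row-level error naming the line."""
    block = df[cols].apply(pd.to_numeric, errors="coerce")
    nonnum = block.isna() & df[cols].notna()
    if nonnum.any().any():
        row = int(np.where(nonnum.any(axis=1))[0][0])
        col = nonnum.columns[nonnum.iloc[row].values][0]
        # +2: header line plus 1-based numbering
        raise TableFormatError(f"{path}: non-numeric value in column {col!r} at line {row + 2}")
    return block


def read_eqtl_table(path, panel: StrainPanel) -> list[EqtlInstance]:
    """Read the DO-eQTL association table.

    Columns: gene_id, gene_chrom, gene_promoter_pos, marker_chrom,
    marker_pos, optional lod, then one allelic-effect column per strain.
    Rows with any missing effect are dropped with a logged report; strain
    columns are reordered to panel order.
    """
    df = _read_tsv(path)
    base = ["gene_id", "gene_chrom", "gene_promoter_pos", "marker_chrom", "marker_pos"]
    _require_columns(df, base + list(panel.strains), path)
    effects = _numeric_block(df, list(panel.strains), path)
    ok = effects.notna().all(axis=1)
    if (~ok).any():
        logger.warning("%s: dropped %d row(s) with missing allelic effects", path, int((~ok).sum()))
    instances = []
    for idx in df.index[ok]:
        row = df.loc[idx]
        instances.append(
            EqtlInstance(
                gene_id=str(row["gene_id"]),
                gene_chrom=str(row["gene_chrom"]),
                gene_promoter_pos=int(row["gene_promoter_pos"]) - 1,
                marker_chrom=str(row["marker_chrom"]),
                marker_pos=int(row["marker_pos"]) - 1,
                allelic_effects=effects.loc[idx].to_numpy(),
                lod=float(row["lod"]) if "lod" in df.columns else float("nan"),
            )
        )
    return instances


def read_snp_table(path, panel: StrainPanel) -> list[CandidateSnp]:
    """Read the candidate-SNP feature table.

    Columns: snp_id, chrom, pos, peak_id, dist_to_promoter, dist_to_marker,
    footprint_flag, effect, effect_pvalue, then geno_<strain> and
    atac_<strain> columns for all 8 strains.
    """
    df = _read_tsv(path)
    base = [
        "snp_id", "chrom", "pos", "peak_id", "dist_to_promoter",
        "dist_to_marker", "footprint_flag", "effect", "effect_pvalue",
    ]
    geno_cols = [f"geno_{s}" for s in panel.strains]
    atac_cols = [f"atac_{s}" for s in panel.strains]
    _require_columns(df, base + geno_cols + atac_cols, path)
    atac = _numeric_block(df, atac_cols, path)
    snps = []
    for idx, row in df.iterrows():
        snps.append(
            CandidateSnp(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]) - 1,
                peak_id=str(row["peak_id"]),
                atac_signal=atac.loc[idx].to_numpy(),
                effect=float(row["effect"]),
                effect_pvalue=float(row["effect_pvalue"]),
                genotypes=row[geno_cols].to_numpy(dtype=int),
                footprint_flag=float(row["footprint_flag"]),
                dist_to_promoter=float(row["dist_to_promoter"]),
                dist_to_marker=float(row["dist_to_marker"]),
            )
        )
    return snps


def read_founder_expression(path, panel: StrainPanel) -> dict[str, FounderExpression]:
    """Read the founder-expression table (gene_id + 8 strain columns)."""
    df = _read_tsv(path)
    _require_columns(df, ["gene_id"] + list(panel.strains), path)
    expr = _numeric_block(df, list(panel.strains), path)
    out = {}
    for idx, row in df.iterrows():
        gid = str(row["gene_id"])
        out[gid] = FounderExpression(gene_id=gid, expression=expr.loc[idx].to_numpy())
    return out


def read_peaks_bed(path) -> pd.DataFrame:
    """Read a BED3+ peak file with peak_id in column 4 (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "peak_id"], usecols=[0, 1, 2, 3],
    )
    if (df["end"] <= df["start"]).any():
        raise TableFormatError(f"{path}: peaks must have end > start")
    return df


def attach_candidates(
    instances: list[EqtlInstance],
    snps: list[CandidateSnp],
    window_bp: int = 1_000_000,
) -> tuple[list[EqtlInstance], int]:
    """Attach candidate SNPs within the marker window to each association.

    Distances to the marker and to the gene promoter are refreshed from the
    coordinates.  Associations with an empty window are excluded from model
    fitting; the count of exclusions is returned and logged.
    """
    import copy

    kept, n_empty = [], 0
    for inst in instances:
        cands = candidate_window(inst.marker_chrom, inst.marker_pos, snps, window_bp)
        if not cands:
            n_empty += 1
            continue
        inst = copy.copy(inst)
        inst.candidates = []
        for c in cands:
            c = copy.copy(c)
            c.dist_to_marker = float(abs(c.pos - inst.marker_pos))
            c.dist_to_promoter = float(abs(c.pos - inst.gene_promoter_pos))
            inst.candidates.append(c)
        kept.append(inst)
    if n_empty:
        logger.warning("excluded %d association(s) with no candidate SNP in window", n_empty)
    return kept, n_empty


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a TSV with ``#`` header lines (version, seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(meta or {})
    meta.setdefault("version", __version__)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_eqtl_table(instances: list[EqtlInstance], panel: StrainPanel, path, meta=None) -> None:
    rows = []
    for inst in instances:
        row = {
            "gene_id": inst.gene_id,
            "gene_chrom": inst.gene_chrom,
            "gene_promoter_pos": inst.gene_promoter_pos + 1,
            "marker_chrom": inst.marker_chrom,
            "marker_pos": inst.marker_pos + 1,
        }
        row.update({s: inst.allelic_effects[i] for i, s in enumerate(panel.strains)})
        rows.append(row)
    write_table(pd.DataFrame(rows), path, meta)


def write_snp_table(snps: list[CandidateSnp], panel: StrainPanel, path, meta=None) -> None:
    rows = []
    for s in snps:
        row = {
            "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos + 1, "peak_id": s.peak_id,
            "dist_to_promoter": s.dist_to_promoter, "dist_to_marker": s.dist_to_marker,
            "footprint_flag": s.footprint_flag, "effect": s.effect,
            "effect_pvalue": s.effect_pvalue,
        }
        row.update({f"geno_{st}": int(s.genotypes[i]) for i, st in enumerate(panel.strains)})
        row.update({f"atac_{st}": s.atac_signal[i] for i, st in enumerate(panel.strains)})
        rows.append(row)
    write_table(pd.DataFrame(rows), path, meta)


def write_founder_expression(
    expr: dict[str, FounderExpression], panel: StrainPanel, path, meta=None
) -> None:
    rows = []
    for gid, fe in expr.items():
        row = {"gene_id": gid}
        row.update({s: fe.expression[i] for i, s in enumerate(panel.strains)})
        rows.append(row)
    write_table(pd.DataFrame(rows), path, meta)
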