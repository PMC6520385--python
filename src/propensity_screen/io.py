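"""Readers and writers for every on-disk format the pipeline touches.

All tabular files are header-bearing UTF-8, tab-separated except the
manifest and panel files (CSV).  Expression data travels as a TSV pair
(intensities, calls) with a ``probe_id`` column followed by ``<line>_<rep>``
sample columns; methylation betas and detection P-values use the same layout
with ``<group>_<rep>`` columns.  Readers validate headers, reject duplicate
probe ids by name, and report malformed cells with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CALL_VALUES, ExpressionDataset, MethylationDataset
from .errors import FormatError
from .ranking import CtTable, PropensityRanking

MANIFEST_COLUMNS = [
    "IlmnID",
    "CHR",
    "MAPINFO",
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "Relation_to_UCSC_CpG_Island",
]


def _sample_columns(lines, n_reps) -> list[str]:
    return [f"{line}_{rep}" for line in lines for rep in range(1, n_reps + 1)]


def _check_duplicates(ids, path) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"{path}: duplicate probe id {i!r}")
        seen.add(i)


def _parse_sample_header(cols, path) -> tuple[list[str], int]:
    """Recover (lines, n_reps) from ``<line>_<rep>`` column names."""
    lines: list[str] = []
    reps_per_line: dict[str, int] = {}
    for c in cols:
        base, _, rep = c.rpartition("_")
        if not base or not rep.isdigit():
            raise FormatError(f"{path}: malformed sample column {c!r} (want <line>_<rep>)")
        if base not in reps_per_line:
            lines.append(base)
            reps_per_line[base] = 0
        reps_per_line[base] += 1
    counts = set(reps_per_line.values())
    if len(counts) != 1:
        raise FormatError(f"{path}: unequal replicate counts per line: {reps_per_line}")
    return lines, counts.pop()


def write_expression(data: ExpressionDataset, intensity_path, calls_path) -> None:
    cols = _sample_columns(data.lines, data.n_replicates)
    flat_i = data.intensity.reshape(data.n_probes, -1)
    flat_c = data.calls.reshape(data.n_probes, -1)
    pd.DataFrame(flat_i, index=pd.Index(data.probe_ids, name="probe_id"), columns=cols).to_csv(
        intensity_path, sep="\t"
    )
    pd.DataFrame(flat_c, index=pd.Index(data.probe_ids, name="probe_id"), columns=cols).to_csv(
        calls_path, sep="\t"
    )


def read_expression(intensity_path, calls_path, normalized: bool = False) -> ExpressionDataset:
    ints = _read_tsv(intensity_path, index_col="probe_id")
    calls = _read_tsv(calls_path, index_col="probe_id")
    _check_duplicates(list(ints.index), intensity_path)
    _check_duplicates(list(calls.index), calls_path)
    if list(ints.columns) != list(calls.columns) or list(ints.index) != list(calls.index):
        raise FormatError("intensity and call files disagree on probes or samples")
    lines, n_reps = _parse_sample_header(ints.columns, intensity_path)
    vals = _numeric_block(ints, intensity_path)
    call_arr = calls.to_numpy(dtype="U1")
    bad = set(np.unique(call_arr)) - CALL_VALUES
    if bad:
        raise FormatError(f"{calls_path}: unknown call values {sorted(bad)}")
    n_probes = vals.shape[0]
    return ExpressionDataset(
        intensity=vals.reshape(n_probes, len(lines), n_reps),
        calls=call_arr.reshape(n_probes, len(lines), n_reps),
        probe_ids=list(ints.index),
        lines=lines,
        normalized=normalized,
    )


def _read_tsv(path, index_col, sep="\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path, sep=sep, dtype=str)
    if index_col not in df.columns:
        raise FormatError(f"{path}: missing required column {index_col!r}")
    return df.set_index(index_col)


def _numeric_block(df: pd.DataFrame, path) -> np.ndarray:
    converted = df.apply(pd.to_numeric, errors="coerce")
    bad = converted.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        col = bad.columns[int(np.argmax(bad.iloc[row].to_numpy()))]
        # +2: header line plus 1-based numbering
        raise FormatError(
            f"{path}: non-numeric cell in column {col!r} at line {row + 2}"
        )
    return converted.to_numpy(dtype=float)


def write_ct_table(table: CtTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_ct_table(path, housekeeping="GAPDH", reference_line="201B7") -> CtTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CtTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["ct"].isna().any():
        row = int(df.index[df["ct"].isna()][0])
        raise FormatError(f"{path}: non-numeric ct value at line {row + 2}")
    return CtTable(data=df, housekeeping=housekeeping, reference_line=reference_line)


def write_panels(panels: dict[str, list[str]], path) -> None:
    rows = [
        {"gene": g, "lineage": lineage}
        for lineage, genes in panels.items()
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_panels(path) -> dict[str, list[str]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path)
    for c in ("gene", "lineage"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    panels: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        panels.setdefault(str(row["lineage"]), []).append(str(row["gene"]))
    return panels


def write_gene_map(gene_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"probe_id": list(gene_map), "gene": [gene_map[p] for p in gene_map]}
    ).to_csv(path, sep="\t", index=False)


def read_gene_map(path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for c in ("probe_id", "gene"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    _check_duplicates(list(df["probe_id"]), path)
    return dict(zip(df["probe_id"], df["gene"]))


def write_methylation(data: MethylationDataset, beta_path, detp_path, manifest_path) -> None:
    cols = [f"{g}_{r}" for g in data.groups for r in range(1, data.n_replicates + 1)]
    idx = pd.Index(data.probe_ids, name="probe_id")
    pd.DataFrame(data.beta.reshape(data.n_probes, -1), index=idx, columns=cols).to_csv(
        beta_path, sep="\t"
    )
    pd.DataFrame(
        data.detection_p.reshape(data.n_probes, -1), index=idx, columns=cols
    ).to_csv(detp_path, sep="\t")
    out = data.manifest.reset_index()
    out.columns = MANIFEST_COLUMNS
    out.to_csv(manifest_path, index=False)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path, dtype={"CHR": str}, keep_default_na=True)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing manifest columns {missing}")
    _check_duplicates(list(df["IlmnID"]), path)
    df = df.set_index("IlmnID")
    df["CHR"] = df["CHR"].fillna("")
    for c in ("UCSC_RefGene_Name", "UCSC_RefGene_Group", "Relation_to_UCSC_CpG_Island"):
        df[c] = df[c].fillna("")
    return df


def read_methylation(beta_path, detp_path, manifest_path, groups=None) -> MethylationDataset:
    beta = _read_tsv(beta_path, index_col="probe_id")
    detp = _read_tsv(detp_path, index_col="probe_id")
    _check_duplicates(list(beta.index), beta_path)
    if list(beta.columns) != list(detp.columns) or list(beta.index) != list(detp.index):
        raise FormatError("beta and detection-P files disagree on probes or samples")
    parsed_groups, n_reps = _parse_sample_header(beta.columns, beta_path)
    manifest = read_manifest(manifest_path)
    vals = _numeric_block(beta, beta_path)
    pvals = _numeric_block(detp, detp_path)
    n = vals.shape[0]
    return MethylationDataset(
        beta=vals.reshape(n, len(parsed_groups), n_reps),
        detection_p=pvals.reshape(n, len(parsed_groups), n_reps),
        manifest=manifest,
        probe_ids=list(beta.index),
        groups=groups or parsed_groups,
    )


def write_ranking(ranking: PropensityRanking, path) -> None:
    pc1 = ranking.pc1_frame().add_suffix("_pc1")
    rank = ranking.rank_frame().add_suffix("_rank")
    pc1.join(rank).to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
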