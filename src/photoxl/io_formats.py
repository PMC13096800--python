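"""Readers and writers for the tabular formats the pipeline touches.

Supported dialects:

* MaxQuant ``proteinGroups`` TSV (per-sample iBAQ/LFQ columns, ``Reverse`` /
  ``Potential contaminant`` markers, peptide and MS/MS counts),
* DIA-NN ``pg_matrix`` / ``pr_matrix`` TSV (one numeric column per run),
* UniProt-style FASTA (via Biopython),
* PDB coordinate files (via gemmi; Calpha atoms only),
* crosslink residue-pair CSV,
* plain TSV results and matrix round-trip files.

Zero intensities are converted to missing (``NaN``) on read: both MaxQuant and
DIA-NN emit 0/blank for absence, and downstream log transforms and imputation
need an explicit missing state. Contaminant / reverse identifications are
flagged (prefix tests ``CON_`` / ``REV_`` on any accession of a group) but not
removed here; removal is a preprocessing step.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    CrosslinkPair,
    FormatError,
    QuantMatrix,
    SampleMeta,
    StructureModel,
)

__all__ = [
    "read_protein_groups",
    "read_pg_matrix",
    "read_pr_matrix",
    "attach_precursor_counts",
    "read_fasta",
    "read_structure",
    "read_crosslinks",
    "read_sample_metadata",
    "attach_sample_metadata",
    "write_results",
    "read_results",
    "write_quant_matrix",
    "read_quant_matrix",
    "write_crosslinks",
]

# float format that round-trips IEEE doubles through text exactly
_FLOAT_FMT = "%.17g"

_PG_ANNOTATION_COLS = {
    "Protein.Group",
    "Protein.Ids",
    "Protein.Names",
    "Genes",
    "First.Protein.Description",
}
_PR_ANNOTATION_COLS = _PG_ANNOTATION_COLS | {
    "Precursor.Id",
    "Precursor.Charge",
    "Modified.Sequence",
    "Stripped.Sequence",
    "Proteotypic",
}


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: missing header / empty file") from exc
    if table.columns.size == 0:
        raise FormatError(f"{path}: missing header")
    return table

def _numeric_block(table: pd.DataFrame, cols: list[str], path) -> np.ndarray:
    """Parse intensity columns to float, zero/blank -> NaN, or fail loudly.

    Values are converted with Python's correctly rounded float parser so a
    write/read cycle is bit-identical.
    """
    out = np.empty((len(table), len(cols)), dtype=float)
    for j, col in enumerate(cols):
        for i, cell in enumerate(table[col]):
            text = cell.strip()
            if text == "" or text.lower() == "nan":
                out[i, j] = np.nan
                continue
            try:
                value = float(text)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric intensity {cell!r} in column "
                    f"{col!r}, row {i}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}: negative intensity {cell!r} in column "
                    f"{col!r}, row {i}"
                )
            out[i, j] = value
    out[out == 0] = np.nan
    return out


def _default_samples(sample_ids: Iterable[str]) -> list[SampleMeta]:
    return [
        SampleMeta(sample_id=sid, condition=sid, replicate=1)
        for sid in sample_ids
    ]


def read_protein_groups(
    path: str | os.PathLike, intensity_prefix: str = "iBAQ "
) -> QuantMatrix:
    """Read a MaxQuant-dialect proteinGroups TSV.

    ``intensity_prefix`` selects the per-sample quantification columns (e.g.
    ``"iBAQ "`` or ``"LFQ intensity "``); sample ids are the column names with
    the prefix stripped.
    """
    table = _read_tsv(path)
    id_col = next(
        (c for c in ("Protein IDs", "Majority protein IDs") if c in table),
        table.columns[0],
    )
    intensity_cols = [
        c
        for c in table.columns
        if c.startswith(intensity_prefix) and c != intensity_prefix.strip()
        and c != f"{intensity_prefix.strip()} peptides"
    ]
    if not intensity_cols:
        raise FormatError(
            f"{path}: no intensity columns matching prefix {intensity_prefix!r}"
        )
    intensities = _numeric_block(table, intensity_cols, path)
    sample_ids = [c[len(intensity_prefix):] for c in intensity_cols]

    ids = table[id_col].tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate protein group ids")

    def _group_has_prefix(group: str, prefix: str) -> bool:
        return any(a.startswith(prefix) for a in str(group).split(";"))

    flags = pd.DataFrame(index=ids)
    rev_col = table["Reverse"] if "Reverse" in table else None
    con_col = next(
        (table[c] for c in ("Potential contaminant", "Contaminant")
         if c in table),
        None,
    )
    flags["reverse"] = [
        _group_has_prefix(g, "REV_")
        or (rev_col is not None and rev_col.iloc[i].strip() == "+")
        for i, g in enumerate(ids)
    ]
    flags["contaminant"] = [
        _group_has_prefix(g, "CON_")
        or (con_col is not None and con_col.iloc[i].strip() == "+")
        for i, g in enumerate(ids)
    ]
    flags["glycoprotein"] = False

    evidence = pd.DataFrame(index=ids)
    if "Peptides" in table:
        evidence["peptides"] = pd.to_numeric(
            table["Peptides"].replace("", "0"), errors="coerce"
        ).fillna(0).astype(int).to_numpy()
    msms_cols = [c for c in table.columns if c.startswith("MS/MS count")]
    if msms_cols:
        counts = np.column_stack(
            [
                pd.to_numeric(table[c].replace("", "0"), errors="coerce")
                .fillna(0)
                .to_numpy()
                for c in msms_cols
            ]
        )
        # maximum spectral count across replicates, the filter's quantity
        evidence["spectral_counts"] = counts.max(axis=1).astype(int)
    if evidence.empty:
        evidence = None

    return QuantMatrix(
        protein_ids=ids,
        intensities=intensities,
        samples=_default_samples(sample_ids),
        evidence=evidence,
        flags=flags,
    )


def read_pg_matrix(path: str | os.PathLike) -> QuantMatrix:
    """Read a DIA-NN ``report.pg_matrix.tsv``-dialect protein-group matrix."""
    table = _read_tsv(path)
    if "Protein.Group" not in table.columns:
        raise FormatError(f"{path}: missing 'Protein.Group' column")
    run_cols = [c for c in table.columns if c not in _PG_ANNOTATION_COLS]
    if not run_cols:
        raise FormatError(f"{path}: no run intensity columns")
    ids = table["Protein.Group"].tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate protein group ids")
    intensities = _numeric_block(table, run_cols, path)
    flags = pd.DataFrame(index=ids)
    flags["contaminant"] = [
        any(a.startswith("CON_") for a in str(g).split(";")) for g in ids
    ]
    flags["reverse"] = [
        any(a.startswith("REV_") for a in str(g).split(";")) for g in ids
    ]
    flags["glycoprotein"] = False
    return QuantMatrix(
        protein_ids=ids,
        intensities=intensities,
        samples=_default_samples(run_cols),
        flags=flags,
    )


def read_pr_matrix(path: str | os.PathLike) -> dict[str, int]:
    """Count quantified precursors per protein group from a pr_matrix TSV.

    Returns, per protein group, the number of distinct precursors with at
    least one non-missing value across runs. Used to exclude proteins
    supported by only a single precursor.
    """
    table = _read_tsv(path)
    for col in ("Protein.Group", "Precursor.Id"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing {col!r} column")
    if (table["Protein.Group"].str.strip() == "").any():
        raise FormatError(f"{path}: precursor row referencing no protein group")
    run_cols = [c for c in table.columns if c not in _PR_ANNOTATION_COLS]
    if not run_cols:
        raise FormatError(f"{path}: no run columns")
    values = _numeric_block(table, run_cols, path)
    quantified = np.isfinite(values).any(axis=1)
    counts: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for i, (group, prec) in enumerate(
        zip(table["Protein.Group"], table["Precursor.Id"])
    ):
        counts.setdefault(group, 0)
        key = (group, prec)
        if quantified[i] and key not in seen:
            seen.add(key)
            counts[group] += 1
    return counts


def attach_precursor_counts(
    qm: QuantMatrix, counts: Mapping[str, int]
) -> QuantMatrix:
    """Attach per-protein precursor counts as evidence (absent -> 0)."""
    out = qm.copy()
    ev = out.evidence if out.evidence is not None else pd.DataFrame(
        index=out.protein_ids
    )
    ev = ev.copy()
    ev["precursors"] = [int(counts.get(p, 0)) for p in out.protein_ids]
    out.evidence = ev
    return out


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA into accession -> uppercase amino-acid sequence.

    The accession is the second ``|``-delimited token of the header when
    present (UniProt style ``sp|P12345|NAME``), else the first
    whitespace-delimited token. ``*`` stop markers are stripped.
    """
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty FASTA")
    out: dict[str, str] = {}
    for rec in records:
        header = rec.id
        accession = header.split("|")[1] if "|" in header else header
        seq = str(rec.seq).upper().replace("*", "")
        if any(ch.isdigit() for ch in seq):
            raise FormatError(f"{path}: sequence for {accession} contains digits")
        out[accession] = seq
    return out


def read_structure(path: str | os.PathLike) -> StructureModel:
    """Read Calpha coordinates from a PDB file.

    Only ATOM records with atom name CA are retained; for alternate locations
    the first altLoc encountered is kept. Author residue numbering is
    preserved per chain. Insertion codes are rejected.
    """
    st = gemmi.read_pdb(os.fspath(path))
    chains: dict[str, dict[int, np.ndarray]] = {}
    if len(st) == 0:
        raise FormatError(f"{path}: no Calpha atoms")
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A":  # ATOM records only
                continue
            for atom in residue:
                if atom.name != "CA" or atom.element.name != "C":
                    continue
                if residue.seqid.icode not in (" ", "", "\x00"):
                    raise FormatError(
                        f"{path}: insertion code at {chain.name}"
                        f"{residue.seqid.num}{residue.seqid.icode} unsupported"
                    )
                res_map = chains.setdefault(chain.name, {})
                if residue.seqid.num in res_map:
                    continue  # first altLoc wins
                res_map[residue.seqid.num] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
                break
    if not any(chains.values()):
        raise FormatError(f"{path}: no Calpha atoms")
    return StructureModel(chains=chains)


def read_crosslinks(path: str | os.PathLike) -> list[CrosslinkPair]:
    """Read a residue-pair CSV.

    Header: ``protein_a,residue_a,protein_b,residue_b[,chain_a,chain_b,score]``.
    """
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: missing header / empty file") from exc
    required = ["protein_a", "residue_a", "protein_b", "residue_b"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    pairs = []
    for i, row in table.iterrows():
        try:
            pairs.append(
                CrosslinkPair(
                    protein_a=row["protein_a"],
                    residue_a=int(row["residue_a"]),
                    protein_b=row["protein_b"],
                    residue_b=int(row["residue_b"]),
                    chain_hint_a=(row.get("chain_a") or None),
                    chain_hint_b=(row.get("chain_b") or None),
                    score=float(row["score"]) if row.get("score") else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: bad crosslink row {i}: {exc}") from exc
    return pairs


def write_crosslinks(pairs: list[CrosslinkPair], path: str | os.PathLike) -> None:
    rows = [
        {
            "protein_a": p.protein_a,
            "residue_a": p.residue_a,
            "protein_b": p.protein_b,
            "residue_b": p.residue_b,
            "chain_a": p.chain_hint_a or "",
            "chain_b": p.chain_hint_b or "",
            "score": "" if p.score is None else p.score,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sample_metadata(path: str | os.PathLike) -> dict[str, SampleMeta]:
    """Read the sidecar sample sheet.

    TSV with columns ``sample_id, condition, time_s, source, replicate``
    (optional ``batch``); neither input dialect encodes irradiation metadata,
    so this sheet carries it.
    """
    table = _read_tsv(path)
    required = ["sample_id", "condition", "time_s", "source", "replicate"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    out = {}
    for _, row in table.iterrows():
        meta = SampleMeta(
            sample_id=row["sample_id"],
            condition=row["condition"],
            irradiation_time=float(row["time_s"]),
            irradiation_source=row["source"],
            replicate=int(row["replicate"]),
            batch=row.get("batch", "") or "",
        )
        out[meta.sample_id] = meta
    return out


def attach_sample_metadata(
    qm: QuantMatrix, meta: Mapping[str, SampleMeta]
) -> QuantMatrix:
    """Replace a matrix's per-sample metadata by sample id."""
    missing = [s.sample_id for s in qm.samples if s.sample_id not in meta]
    if missing:
        raise FormatError(f"no metadata for samples: {missing}")
    out = qm.copy()
    out.samples = [meta[s.sample_id] for s in qm.samples]
    return QuantMatrix(  # re-validate uniqueness invariants
        protein_ids=out.protein_ids,
        intensities=out.intensities,
        samples=out.samples,
        evidence=out.evidence,
        flags=out.flags,
        log=out.log,
    )


def write_results(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table as TSV; floats round-trip bit-identically."""
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_quant_matrix(
    qm: QuantMatrix,
    matrix_path: str | os.PathLike,
    meta_path: str | os.PathLike,
) -> None:
    """Serialize a QuantMatrix as a matrix TSV plus a sample-sheet TSV.

    Missing intensities are written as 0, mirroring the zero-as-missing
    convention of the input dialects, so write -> read is an identity.
    """
    frame = pd.DataFrame({"protein_id": qm.protein_ids})
    for col in qm.flags.columns:
        frame[f"flag_{col}"] = qm.flags[col].astype(int).to_numpy()
    if qm.evidence is not None:
        for col in qm.evidence.columns:
            frame[f"evidence_{col}"] = (
                qm.evidence[col].fillna(0).astype(int).to_numpy()
            )
    values = np.nan_to_num(qm.intensities, nan=0.0)
    for j, sid in enumerate(qm.sample_ids):
        frame[sid] = values[:, j]
    frame.to_csv(matrix_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    meta_rows = [
        {
            "sample_id": s.sample_id,
            "condition": s.condition,
            "time_s": s.irradiation_time,
            "source": s.irradiation_source,
            "replicate": s.replicate,
            "batch": s.batch,
        }
        for s in qm.samples
    ]
    pd.DataFrame(meta_rows).to_csv(
        meta_path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_quant_matrix(
    matrix_path: str | os.PathLike, meta_path: str | os.PathLike
) -> QuantMatrix:
    """Inverse of :func:`write_quant_matrix`."""
    table = _read_tsv(matrix_path)
    if "protein_id" not in table.columns:
        raise FormatError(f"{matrix_path}: missing 'protein_id' column")
    ids = table["protein_id"].tolist()
    flag_cols = [c for c in table.columns if c.startswith("flag_")]
    ev_cols = [c for c in table.columns if c.startswith("evidence_")]
    sample_cols = [
        c
        for c in table.columns
        if c != "protein_id" and c not in flag_cols and c not in ev_cols
    ]
    intensities = _numeric_block(table, sample_cols, matrix_path)
    flags = pd.DataFrame(index=ids)
    for c in flag_cols:
        flags[c[len("flag_"):]] = (
            pd.to_numeric(table[c]).astype(bool).to_numpy()
        )
    evidence = None
    if ev_cols:
        evidence = pd.DataFrame(index=ids)
        for c in ev_cols:
            evidence[c[len("evidence_"):]] = (
                pd.to_numeric(table[c]).astype(int).to_numpy()
            )
    meta = read_sample_metadata(meta_path)
    samples = [meta[sid] for sid in sample_cols]
    return QuantMatrix(
        protein_ids=ids,
        intensities=intensities,
        samples=samples,
        evidence=evidence,
        flags=flags,
    )
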