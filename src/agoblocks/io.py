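"""Readers and writers for external formats and the packaged fixtures.

Conventions
-----------
* All coordinates in external files are 1-based inclusive (the Pfam batch
  convention); internal computations are 0-based half-open and convert at
  this boundary.
* Non-standard residues (B, Z, J, U, O, ``*``) collapse to ``X`` on input;
  ``X`` contributes background probability in all downstream scoring.
* FASTA output wraps sequences at 60 columns.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .models import (
    AMINO_ACIDS,
    Architecture,
    BlockModel,
    BlockOccurrence,
    CodingSequence,
    DomainAnnotation,
    DomainSeries,
    NONSTANDARD,
    ProteinRecord,
    unique_ids,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def normalize_protein(seq: str) -> tuple[str, int]:
    """Uppercase and collapse non-standard residues to 'X'.

    Returns the normalized sequence and the number of replaced characters.
    """
    seq = seq.upper()
    replaced = sum(1 for c in seq if c in NONSTANDARD)
    if replaced:
        seq = "".join("X" if c in NONSTANDARD else c for c in seq)
    bad = set(seq) - set(AMINO_ACIDS) - {"X"}
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return seq, replaced


def _check_fasta_header(path: PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: not FASTA (line {lineno} does not start with '>')"
                    )
                return
    raise ValueError(f"{path}: empty FASTA file")


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Record ids are the first whitespace-delimited header token; sequences are
    uppercased and non-standard residues mapped to 'X' (one warning logged
    per affected record).  Duplicate ids and empty files raise ``ValueError``.
    """
    _check_fasta_header(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, replaced = normalize_protein(str(rec.seq))
        if replaced:
            logger.warning(
                "%s: %d non-standard residue(s) replaced with 'X'", rec.id, replaced
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    unique_ids(records)
    return records


def read_cds_fasta(path: PathLike) -> list[CodingSequence]:
    """Read a nucleotide FASTA file into :class:`CodingSequence` objects."""
    _check_fasta_header(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        nt = str(rec.seq).upper().replace("U", "T")
        records.append(CodingSequence(id=rec.id, nucleotides=nt))
    unique_ids(records)
    return records


def write_fasta(records: Iterable, path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.sequence if isinstance(rec, ProteinRecord) else rec.nucleotides
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Block table (packaged transcription of the 50 plant AGO blocks)
# ---------------------------------------------------------------------------

_TAG_ALIASES = {"-": "NONE", "–": "NONE", "NONE": "NONE"}


def load_block_table(path: PathLike, match_prob: float = 0.9) -> list[BlockModel]:
    """Load a tab-separated block table into :class:`BlockModel` objects.

    Expected columns: ``block_id``, ``length``, ``consensus``, ``domain_tag``
    (and an optional free-text ``comment``).  Each model's matrix puts
    ``match_prob`` on the consensus residue of every column and spreads the
    remainder uniformly over the other 19 residues.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    models = []
    if df.empty:
        return models
    for _, row in df.iterrows():
        block_id = int(row["block_id"])
        consensus = row["consensus"].strip()
        declared = int(row["length"])
        if declared != len(consensus):
            raise ValueError(
                f"block {block_id}: declared length {declared} != "
                f"consensus length {len(consensus)}"
            )
        tag = row["domain_tag"].strip()
        if tag in _TAG_ALIASES:
            tag = _TAG_ALIASES[tag]
        elif tag not in ("PIWI", "PAZ", "DUF1785"):
            raise ValueError(f"block {block_id}: unknown domain tag {tag!r}")
        models.append(
            BlockModel.from_consensus(
                block_id, consensus, match_prob=match_prob, domain_tag=tag
            )
        )
    return models


def packaged_path(name: str) -> Path:
    return Path(str(resources.files("agoblocks").joinpath("data", name)))


def load_packaged_blocks(match_prob: float = 0.9) -> list[BlockModel]:
    """The 50 plant AGO consensus blocks shipped with the package."""
    return load_block_table(packaged_path("block_table.tsv"), match_prob=match_prob)


def load_series_catalog(path: Optional[PathLike] = None) -> list[DomainSeries]:
    """The named domain-series catalog (A/B/DUF1785/PAZ/PIWI variants)."""
    if path is None:
        path = packaged_path("series_catalog.tsv")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for _, row in df.iterrows():
        blocks = tuple(int(b) for b in row["blocks"].split("-"))
        out.append(
            DomainSeries(
                name=row["name"], blocks=blocks, domain_class=row["domain_class"]
            )
        )
    return out


def load_clade_table(path: Optional[PathLike] = None) -> pd.DataFrame:
    """Per-clade member counts, consensus series, specific blocks, repeat block."""
    if path is None:
        path = packaged_path("clade_catalog.tsv")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df["n_members"] = df["n_members"].astype(int)
    df["series"] = df["series"].apply(lambda s: s.split(";"))
    df["specific_blocks"] = df["specific_blocks"].apply(
        lambda s: [] if s.strip() == "-" else [int(x) for x in s.split(",")]
    )
    # keep dtype=object so "no repeat" rows stay None instead of NaN
    df["repeat_block"] = pd.array(
        [None if s.strip() == "-" else int(s) for s in df["repeat_block"]],
        dtype=object,
    )
    return df


def clade_architectures(
    clade_table: Optional[pd.DataFrame] = None,
    catalog: Optional[Sequence[DomainSeries]] = None,
) -> dict[str, list[int]]:
    """Expand each clade's named series into its full ordered block list."""
    if clade_table is None:
        clade_table = load_clade_table()
    if catalog is None:
        catalog = load_series_catalog()
    by_name = {s.name: s for s in catalog}
    out: dict[str, list[int]] = {}
    for _, row in clade_table.iterrows():
        arch: list[int] = []
        for name in row["series"]:
            if name not in by_name:
                raise ValueError(f"clade {row['clade']}: unknown series {name!r}")
            arch.extend(by_name[name].blocks)
        out[row["clade"]] = arch
    return out


# ---------------------------------------------------------------------------
# Group assignments
# ---------------------------------------------------------------------------

def read_group_assignments(path: PathLike) -> dict[str, str]:
    """Read a two-column tab-separated protein_id -> group table.

    A protein appearing twice with different labels raises ``ValueError``.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("protein_id", "id", "protein"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            pid, group = parts[0], parts[1]
            if pid in mapping and mapping[pid] != group:
                raise ValueError(
                    f"protein {pid!r} assigned to both {mapping[pid]!r} and {group!r}"
                )
            mapping[pid] = group
    return mapping


def groups_from_tree(
    newick_path: PathLike, exemplars: Union[PathLike, Mapping[str, str]]
) -> dict[str, str]:
    """Label every tree leaf with the clade of its nearest labeled exemplar.

    Distance is patristic path length; ties go to the lexicographically
    smallest exemplar id.  ``exemplars`` maps exemplar leaf id -> clade label
    (or is a two-column TSV of the same).
    """
    if not isinstance(exemplars, Mapping):
        exemplars = read_group_assignments(exemplars)
    tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = set(exemplars) - set(taxa)
    if missing:
        raise ValueError(f"exemplars not found as tree leaves: {sorted(missing)}")
    if not exemplars:
        raise ValueError("no exemplars supplied; leaves are unreachable")
    mapping: dict[str, str] = {}
    for leaf_label, leaf_taxon in taxa.items():
        if leaf_label in exemplars:
            mapping[leaf_label] = exemplars[leaf_label]
            continue
        best = min(
            sorted(exemplars),
            key=lambda ex: (pdm.patristic_distance(leaf_taxon, taxa[ex]), ex),
        )
        mapping[leaf_label] = exemplars[best]
    return mapping


def write_group_assignments(mapping: Mapping[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgroup\n")
        for pid, group in mapping.items():
            fh.write(f"{pid}\t{group}\n")


# ---------------------------------------------------------------------------
# Domain annotations (Pfam-batch-like TSV)
# ---------------------------------------------------------------------------

def read_annotations(path: PathLike) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for _, row in df.iterrows():
        score = row.get("score")
        out.append(
            DomainAnnotation(
                protein_id=row["protein_id"],
                domain=row["domain"],
                start=int(row["start"]),
                end=int(row["end"]),
                score=None if score in (None, "", "nan") or pd.isna(score) else float(score),
            )
        )
    return out


def write_annotations(annotations: Iterable[DomainAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain\tstart\tend\tscore\n")
        for a in annotations:
            score = "" if a.score is None else f"{a.score:g}"
            fh.write(f"{a.protein_id}\t{a.domain}\t{a.start}\t{a.end}\t{score}\n")


# ---------------------------------------------------------------------------
# Architectures (scan output TSV)
# ---------------------------------------------------------------------------

def write_architectures(architectures: Iterable[Architecture], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tblock_id\tstart\twidth\tscore_bits\tp_value\n")
        for arch in architectures:
            for o in arch.occurrences:
                fh.write(
                    f"{o.protein_id}\t{o.block_id}\t{o.start}\t{o.width}\t"
                    f"{o.score:.2f}\t{o.p_value:.3e}\n"
                )


def read_architectures(path: PathLike) -> list[Architecture]:
    df = pd.read_csv(path, sep="\t", comment="#")
    archs = []
    for pid, sub in df.groupby("protein_id", sort=False):
        occs = [
            BlockOccurrence(
                protein_id=str(pid),
                block_id=int(r.block_id),
                start=int(r.start),
                score=float(r.score_bits),
                p_value=float(r.p_value),
                width=int(r.width),
            )
            for r in sub.itertuples()
        ]
        archs.append(Architecture(protein_id=str(pid), occurrences=occs))
    return archs


# ---------------------------------------------------------------------------
# Block-model serialization (documented text format)
# ---------------------------------------------------------------------------

_MODEL_HEADER = re.compile(
    r"^>block (?P<id>\d+) width (?P<w>\d+) tag (?P<tag>\S+)$"
)


def _quantize(v: np.ndarray) -> np.ndarray:
    # Largest-remainder rounding to multiples of 1e-6 so each written
    # distribution sums exactly to 1 (keeps the BlockModel column-sum
    # invariant intact across a round-trip) while every entry stays within
    # 1e-6 of the original.
    units = np.floor(v * 1e6).astype(np.int64)
    short = int(round(1e6 - units.sum()))
    if short > 0:
        remainders = v * 1e6 - units
        for idx in np.argsort(-remainders, kind="stable")[:short]:
            units[idx] += 1
    return units / 1e6


def serialize_block_models(models: Sequence[BlockModel], path: PathLike) -> None:
    """Write models to the package's text model format (6 decimal places).

    Format: a ``# agoblocks models v1`` header, then per model a
    ``>block <id> width <w> tag <tag>`` line, one ``background`` line of 20
    probabilities, and ``w`` matrix rows of 20 probabilities each.
    """
    with open(path, "w") as fh:
        fh.write("# agoblocks models v1\n")
        for m in models:
            fh.write(f">block {m.block_id} width {m.width} tag {m.domain_tag}\n")
            bg = _quantize(m.background)
            fh.write("background " + " ".join(f"{p:.6f}" for p in bg) + "\n")
            for row in m.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in _quantize(row)) + "\n")


def deserialize_block_models(path: PathLike) -> list[BlockModel]:
    models: list[BlockModel] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    i = 0
    while i < len(lines):
        match = _MODEL_HEADER.match(lines[i])
        if not match:
            raise ValueError(
                f"{path}: record {len(models) + 1}: expected model header, "
                f"got {lines[i]!r}"
            )
        width = int(match["w"])
        need = width + 2
        if i + need > len(lines):
            raise ValueError(
                f"{path}: record {len(models) + 1}: truncated (expected "
                f"{width} matrix rows)"
            )
        bg_line = lines[i + 1]
        if not bg_line.startswith("background "):
            raise ValueError(f"{path}: record {len(models) + 1}: missing background")
        background = np.array([float(x) for x in bg_line.split()[1:]])
        rows = []
        for j in range(width):
            vals = [float(x) for x in lines[i + 2 + j].split()]
            if len(vals) != 20:
                raise ValueError(
                    f"{path}: record {len(models) + 1}: matrix row {j + 1} has "
                    f"{len(vals)} values"
                )
            rows.append(np.array(vals))
        models.append(
            BlockModel(
                block_id=int(match["id"]),
                matrix=np.vstack(rows),
                background=background,
                domain_tag=match["tag"],
            )
        )
        i += need
    return models
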