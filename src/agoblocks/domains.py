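"""Canonical-domain preprocessing: filtering and coding-sequence extraction.

AGO proteins are defined by their PAZ and PIWI domains; sequences lacking
either are treated as misannotations and discarded.  For kept proteins the
coding-sequence segments encoding the DUF1785, PAZ and PIWI domains are
sliced out using the (1-based, inclusive) amino-acid coordinates of a
Pfam-style batch annotation, merged where they overlap or abut, and
concatenated in coordinate order — eliminating inter-domain regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .models import CodingSequence, DomainAnnotation, ProteinRecord

CANONICAL_DOMAINS = frozenset({"PAZ", "PIWI"})
DEFAULT_EXTRACT = frozenset({"DUF1785", "PAZ", "PIWI"})


@dataclass
class ExtractionResult:
    """Outcome of domain extraction for one protein."""

    protein_id: str
    kept: bool
    extracted_cds: str
    extracted_aa: str
    segments: list[tuple[str, int, int]]  # (domain, aa_start, aa_end), merged


def filter_canonical(
    annotations: Iterable[DomainAnnotation], protein_ids: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Split proteins into (kept, discarded) by the canonical-domain rule.

    A protein is kept iff it has at least one PAZ and at least one PIWI
    annotation; DUF1785 is not required.  An annotation referencing an
    unknown protein raises ``ValueError``.
    """
    ids = set(protein_ids)
    have: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.protein_id not in ids:
            raise ValueError(f"annotation references unknown protein {ann.protein_id!r}")
        have.setdefault(ann.protein_id, set()).add(ann.domain)
    kept = {pid for pid in ids if CANONICAL_DOMAINS <= have.get(pid, set())}
    return kept, ids - kept


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; overlapping or bookended
    (end + 1 == next start) intervals merge."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def translate_cds(nucleotides: str) -> str:
    """Standard-table translation, trimmed at the first stop."""
    aa = str(Seq(nucleotides).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def extract_domain_cds(
    cds: CodingSequence,
    protein: ProteinRecord,
    annotations: Iterable[DomainAnnotation],
    domains: frozenset[str] = DEFAULT_EXTRACT,
) -> ExtractionResult:
    """Extract and concatenate the CDS segments encoding the given domains.

    Amino-acid interval [s, e] (1-based inclusive) maps to nucleotide
    interval [3s-2, 3e].  Overlapping or bookended annotations of any
    requested domain are merged before extraction; segments are concatenated
    in ascending coordinate order, preserving the protein's linear layout.
    """
    L = len(protein.sequence)
    n_coding = len(cds.nucleotides)
    if n_coding % 3:
        raise ValueError(f"{cds.id}: CDS length {n_coding} not a multiple of 3")
    # allow a trailing stop codon
    if n_coding not in (3 * L, 3 * (L + 1)):
        raise ValueError(
            f"{cds.id}: CDS length {n_coding} does not match protein length {L}"
        )
    spans: list[tuple[int, int, str]] = []
    for ann in annotations:
        if ann.protein_id != protein.id:
            continue
        if ann.domain not in domains:
            continue
        if ann.end > L:
            raise ValueError(
                f"{protein.id}/{ann.domain}: annotation end {ann.end} beyond "
                f"protein length {L}"
            )
        spans.append((ann.start, ann.end, ann.domain))
    merged = merge_intervals([(s, e) for s, e, _ in spans])
    # after merging, label each merged interval with the domains it absorbed
    segments: list[tuple[str, int, int]] = []
    for s, e in merged:
        names = sorted({d for ms, me, d in spans if ms <= e and me >= s})
        segments.append(("+".join(names), s, e))
    aa_parts, nt_parts = [], []
    for _, s, e in segments:
        aa_parts.append(protein.sequence[s - 1 : e])
        nt_parts.append(cds.nucleotides[3 * (s - 1) : 3 * e])
    return ExtractionResult(
        protein_id=protein.id,
        kept=True,
        extracted_cds="".join(nt_parts),
        extracted_aa="".join(aa_parts),
        segments=segments,
    )


def extract_family(
    proteins: Sequence[ProteinRecord],
    cds_records: Sequence[CodingSequence],
    annotations: Sequence[DomainAnnotation],
    domains: frozenset[str] = DEFAULT_EXTRACT,
) -> tuple[list[ExtractionResult], set[str], set[str]]:
    """Filter a whole family and extract domain CDS for the kept proteins.

    Returns (results, kept_ids, discarded_ids); discarded proteins get an
    empty extraction result with ``kept=False``.
    """
    kept, discarded = filter_canonical(annotations, [p.id for p in proteins])
    cds_by_id = {c.id: c for c in cds_records}
    results = []
    for prot in proteins:
        if prot.id not in kept:
            results.append(
                ExtractionResult(prot.id, False, "", "", segments=[])
            )
            continue
        results.append(
            extract_domain_cds(cds_by_id[prot.id], prot, annotations, domains)
        )
    return results, kept, discarded
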