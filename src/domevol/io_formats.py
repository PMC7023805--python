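"""Readers and writers for the file formats the pipeline touches.

Supported inputs:

* Newick species trees (via :class:`domevol.tree.PhyloTree` / dendropy);
* ``pfam_scan.pl`` (version 1.5) whitespace-delimited tabular output, one
  domain hit per line;
* the simplified *arrangement TSV* dialect: two tab-separated columns,
  ``protein_id`` and a dash-separated canonical arrangement, ``#`` comments
  allowed;
* a two-column manifest mapping species ids to annotation files.

Outputs are plain TSV/JSON result tables.  The longest-isoform filter used
for proteome preprocessing also lives here.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple, Union

from .arrangements import ArrangementSet, DomainArrangement, collapse_repeats
from .errors import FormatError, ValidationError
from .tree import PhyloTree

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_newick(text: str, outgroup: Iterable[str] = (),
                resolve_root: bool = False) -> PhyloTree:
    """Parse a rooted Newick tree; see :meth:`PhyloTree.from_newick`."""
    return PhyloTree.from_newick(text, outgroup=outgroup, resolve_root=resolve_root)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


@dataclass(frozen=True)
class PfamHit:
    """One domain hit from pfam_scan output (post-threshold; carried as-is)."""

    protein_id: str
    ali_start: int
    ali_end: int
    accession: str
    name: str
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValidationError(
                f"hit on {self.protein_id}: ali_start {self.ali_start} > ali_end {self.ali_end}"
            )
        if not self.accession:
            raise ValidationError(f"hit on {self.protein_id}: empty accession")


@dataclass
class SpeciesAnnotation:
    """Domain arrangements of one species' proteome.

    ``proteins`` maps protein id to its canonical arrangement; ``repertoire``
    is the deduplicated presence/absence set over all proteins.
    """

    species_id: str
    proteins: Dict[str, DomainArrangement]
    repertoire: ArrangementSet = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        derived = ArrangementSet(self.proteins.values())
        if self.repertoire is None:
            self.repertoire = derived
        elif self.repertoire != derived:
            raise ValidationError(
                f"{self.species_id}: repertoire does not match the protein mapping"
            )


def _iter_lines(source) -> Iterable[Tuple[int, str]]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from enumerate(fh, start=1)
    else:
        yield from enumerate(source, start=1)


def read_pfamscan(source) -> List[PfamHit]:
    """Read pfam_scan.pl v1.5 tabular output (path or iterable of lines).

    Column layout: seq id, alignment start/end, envelope start/end, hmm acc,
    hmm name, type, hmm start/end/length, bit score, E-value, significance,
    clan.  Lines starting with ``#`` and blank lines are skipped.  No
    filtering is applied here: pfam_scan has already applied the Pfam
    gathering thresholds upstream.
    """
    hits: List[PfamHit] = []
    for lineno, line in _iter_lines(source):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 7:
            raise FormatError(
                f"pfam_scan line {lineno}: expected >= 7 whitespace-separated "
                f"fields, got {len(fields)}"
            )
        try:
            hit = PfamHit(
                protein_id=fields[0],
                ali_start=int(fields[1]),
                ali_end=int(fields[2]),
                accession=fields[5],
                name=fields[6],
                evalue=float(fields[12]) if len(fields) > 12 else 0.0,
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"pfam_scan line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def build_annotation(hits: Sequence[PfamHit], species_id: str) -> SpeciesAnnotation:
    """Turn per-protein domain hits into canonical arrangements.

    Hits are sorted by alignment start (linear order on the sequence), the
    accession sequence is repeat-collapsed, and the repertoire is the
    distinct set over proteins.  Overlapping hits on one protein are both
    kept, ordered by start, with a logged warning.
    """
    per_protein: Dict[str, List[PfamHit]] = {}
    for hit in hits:
        per_protein.setdefault(hit.protein_id, []).append(hit)
    proteins: Dict[str, DomainArrangement] = {}
    for pid, phits in per_protein.items():
        ordered = sorted(phits, key=lambda h: (h.ali_start, h.ali_end))
        for a, b in zip(ordered, ordered[1:]):
            if b.ali_start <= a.ali_end:
                logger.warning(
                    "%s/%s: overlapping hits %s@(%d,%d) and %s@(%d,%d); keeping both",
                    species_id, pid, a.accession, a.ali_start, a.ali_end,
                    b.accession, b.ali_start, b.ali_end,
                )
        proteins[pid] = collapse_repeats(h.accession for h in ordered)
    return SpeciesAnnotation(species_id=species_id, proteins=proteins)


def longest_isoform_filter(
    records: Mapping[str, Sequence[Tuple[str, int]]]
) -> Set[str]:
    """Keep exactly one protein per gene: the longest isoform.

    ``records`` maps gene id to ``(protein_id, length)`` pairs.  Ties on
    length are broken by the lexicographically smallest protein id, for
    determinism.
    """
    keep: Set[str] = set()
    for gene, isoforms in records.items():
        if not isoforms:
            raise ValidationError(f"gene {gene!r} has no isoforms")
        for pid, length in isoforms:
            if length <= 0:
                raise ValidationError(f"gene {gene!r}: isoform {pid!r} has non-positive length")
        best = min(isoforms, key=lambda pl: (-pl[1], pl[0]))
        keep.add(best[0])
    return keep


# ---------------------------------------------------------------------------
# arrangement TSV dialect


def read_arrangements_tsv(source, species_id: str) -> SpeciesAnnotation:
    """Read the two-column arrangement TSV (protein id, dash-separated
    arrangement).  Arrangements are canonicalized on ingest."""
    proteins: Dict[str, DomainArrangement] = {}
    for lineno, line in _iter_lines(source):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"arrangement TSV line {lineno}: expected 2 tab-separated columns, "
                f"got {len(parts)}"
            )
        pid, text = parts
        if pid in proteins:
            raise FormatError(f"arrangement TSV line {lineno}: duplicate protein id {pid!r}")
        try:
            proteins[pid] = collapse_repeats(text.split("-"))
        except ValidationError as exc:
            raise FormatError(f"arrangement TSV line {lineno}: {exc}") from exc
    return SpeciesAnnotation(species_id=species_id, proteins=proteins)


def write_arrangements_tsv(annotation: SpeciesAnnotation, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# species: {annotation.species_id}\n")
        for pid in sorted(annotation.proteins):
            fh.write(f"{pid}\t{annotation.proteins[pid]}\n")


def read_manifest(path: PathLike) -> List[Tuple[str, Path]]:
    """Read a manifest TSV of (species_id, annotation path); relative paths
    are resolved against the manifest's directory."""
    base = Path(path).parent
    entries: List[Tuple[str, Path]] = []
    for lineno, line in _iter_lines(path):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 2:
            raise FormatError(f"manifest line {lineno}: expected 2 columns")
        species, p = parts
        fp = Path(p)
        if not fp.is_absolute():
            fp = base / fp
        entries.append((species, fp))
    return entries


# ---------------------------------------------------------------------------
# result writers (TSV/JSON); the objects themselves live in events/rates


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_state_dump_tsv(matrix, path: PathLike) -> None:
    """Per-node character states (node_id, character, state) for debugging."""
    from .parsimony import TriState

    with open(path, "w") as fh:
        fh.write("node_id\tcharacter\tstate\n")
        for node_id in matrix.node_ids:
            for char in matrix.characters:
                state = TriState(matrix.state(node_id, char)).name.lower()
                fh.write(f"{node_id}\t{char}\t{state}\n")
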