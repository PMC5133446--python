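"""Cross-species comparison of readthrough extensions and PTS1 strength.

Extensions are compared in a C-terminal-anchored alignment: the C-terminus
is the biologically aligned end (it carries the PTS1 tripeptide), so rows
are right-justified and padded on the left.  Per column, conservation is
the fraction held by the most frequent residue.  The clade contrast scores
each extension's C-terminus with a PTS1 model and compares clade means
(mammals carry CRL-type termini, non-mammalian vertebrates SRL-type).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from readthrough import pts1_model as _pts1

GAP_CHAR = "-"
MAMMAL = "mammal"
NON_MAMMAL = "non-mammal-vertebrate"
OTHER = "other"


@dataclass(frozen=True)
class OrthologueEntry:
    species: str
    clade: str
    extension: str


@dataclass(frozen=True)
class OrthologueSet:
    entries: tuple[OrthologueEntry, ...]

    def clade(self, name: str) -> list[OrthologueEntry]:
        return [e for e in self.entries if e.clade == name]


@dataclass(frozen=True)
class AlignedExtensions:
    rows: tuple[str, ...]  # left-padded, equal length
    species: tuple[str, ...]
    conservation: tuple[float, ...]  # per column, modal-residue fraction


def read_orthologues(fasta: str | Path) -> OrthologueSet:
    """Load an orthologue extension set from FASTA with ``clade=`` header tokens."""
    entries = []
    for record in SeqIO.parse(str(fasta), "fasta"):
        clade = None
        for token in record.description.split():
            if token.startswith("clade="):
                clade = token.split("=", 1)[1]
        if clade is None:
            raise ValueError(f"{record.id}: missing clade= header token")
        entries.append(
            OrthologueEntry(species=record.id, clade=clade, extension=str(record.seq).upper())
        )
    return OrthologueSet(entries=tuple(entries))


def align_extensions(oset: OrthologueSet) -> AlignedExtensions:
    """C-terminal-anchored alignment with per-column conservation.

    Conservation in a column is computed over the non-gap residues only,
    as (count of modal residue) / (non-gap rows in the column).
    """
    if not oset.entries:
        raise ValueError("empty orthologue set")
    if len(oset.entries) < 2:
        raise ValueError("alignment requires at least 2 entries")
    width = max(len(e.extension) for e in oset.entries)
    rows = tuple(e.extension.rjust(width, GAP_CHAR) for e in oset.entries)
    conservation = []
    for col in range(width):
        residues = [r[col] for r in rows if r[col] != GAP_CHAR]
        counts = {aa: residues.count(aa) for aa in set(residues)}
        conservation.append(max(counts.values()) / len(residues))
    return AlignedExtensions(
        rows=rows,
        species=tuple(e.species for e in oset.entries),
        conservation=tuple(conservation),
    )


def terminal_tripeptides(oset: OrthologueSet) -> dict[str, set[str]]:
    """Terminal tripeptide classes observed per clade."""
    out: dict[str, set[str]] = {}
    for e in oset.entries:
        if len(e.extension) < 3:
            raise ValueError(f"{e.species}: extension shorter than a tripeptide")
        out.setdefault(e.clade, set()).add(e.extension[-3:])
    return out


@dataclass(frozen=True)
class CladeContrast:
    mean_mammal: float
    mean_nonmammal: float
    direction: int  # sign of (non-mammal − mammal)


def clade_pts1_contrast(
    oset: OrthologueSet, model: Optional[_pts1.PTS1Model] = None
) -> CladeContrast:
    """Mean PTS1 probability per clade and the sign of the difference.

    Entries with clade ``other`` (e.g. amphibian exceptions) are excluded.
    """
    model = model or _pts1.default_model()
    mammals = oset.clade(MAMMAL)
    nonmammals = oset.clade(NON_MAMMAL)
    if not mammals or not nonmammals:
        raise ValueError("both mammal and non-mammal-vertebrate clades must be non-empty")

    def mean_prob(entries: Sequence[OrthologueEntry]) -> float:
        probs = [_pts1.score_pts1(model, e.extension).probability for e in entries]
        return sum(probs) / len(probs)

    m = mean_prob(mammals)
    nm = mean_prob(nonmammals)
    diff = nm - m
    return CladeContrast(mean_mammal=m, mean_nonmammal=nm, direction=(diff > 0) - (diff < 0))


def packaged_orthologue_fixture() -> OrthologueSet:
    """Synthetic vertebrate MDH1x-style extension set (CRL mammals, SRL others)."""
    path = resources.files("readthrough.data").joinpath("orthologue_extensions.fasta")
    with resources.as_file(path) as p:
        return read_orthologues(p)
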