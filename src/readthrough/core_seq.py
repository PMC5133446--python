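"""Sequence data model: transcripts, stop-codon contexts, readthrough extensions.

Coordinate convention: transcript positions are 1-based; relative to the
annotated stop codon, the stop occupies +1..+3 and the first 3' base is +4
(so "position +4" is the first nucleotide after the stop). Sequences are
normalized to RNA (T -> U) on load and all motifs are stored as RNA.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: Placeholder for the residue encoded by the suppressed stop codon.
READTHROUGH_PLACEHOLDER = "X"

_STANDARD_TABLE = CodonTable.unambiguous_rna_by_id[1]

#: codon -> one-letter residue, standard genetic code, '*' for stops.
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"


class AmbiguousBaseError(ValueError):
    """Raised when a codon contains a base outside A/C/G/U."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA (T) to RNA (U)."""
    return seq.strip().upper().replace("T", "U")


def translate(nt: str) -> str:
    """Translate an RNA string with the standard genetic code.

    Length must be divisible by 3; stop codons translate to ``'*'``.
    Raises :class:`AmbiguousBaseError` for any non-A/C/G/U base.
    """
    nt = normalize_rna(nt)
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} not divisible by 3")
    residues = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        try:
            residues.append(CODON_TO_AA[codon])
        except KeyError:
            raise AmbiguousBaseError(f"cannot translate codon {codon!r}") from None
    return "".join(residues)


@dataclass(frozen=True)
class Transcript:
    """A transcript (or CDS fragment) with an annotated stop codon.

    ``stop_start`` is the 1-based index of the first nucleotide of the
    annotated stop codon.  ``is_control`` marks sense-codon controls (e.g.
    a UGG construct standing in for 100% readthrough), which are allowed
    to carry a non-stop triplet at ``stop_start``.
    """

    id: str
    seq: str
    stop_start: int
    species: Optional[str] = None
    is_control: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if self.stop_start < 1:
            raise ValueError(f"{self.id}: stop_start must be >= 1")
        if self.stop_start + 2 > len(self.seq):
            raise ValueError(f"{self.id}: stop codon extends past sequence end")
        if self.stop_codon not in STOP_CODONS and not self.is_control:
            raise ValueError(
                f"{self.id}: {self.stop_codon!r} at stop_start is a sense codon "
                "(flag the record is_control=True if intentional)"
            )

    @property
    def stop_codon(self) -> str:
        return self.seq[self.stop_start - 1 : self.stop_start + 2]


@dataclass(frozen=True)
class StopCodonContext:
    """The stop codon plus positional flanks (the SCC).

    ``upstream`` runs -1..-U with the -1 base adjacent to the stop;
    ``downstream`` runs +4..+(3+D).  ``truncated`` is set when the requested
    flanks extended past the transcript and were clipped.
    """

    stop: str
    upstream: str
    downstream: str
    truncated: bool = False

    @property
    def u_len(self) -> int:
        return len(self.upstream)

    @property
    def d_len(self) -> int:
        return len(self.downstream)

    def reassemble(self) -> str:
        """The contiguous source subsequence upstream+stop+downstream."""
        return self.upstream + self.stop + self.downstream

    def base_at(self, position: int) -> str:
        """Base at a stop-relative position (+1..+3 stop, +4.. downstream, -1.. upstream)."""
        if 1 <= position <= 3:
            return self.stop[position - 1]
        if position >= 4:
            idx = position - 4
            if idx >= self.d_len:
                raise IndexError(f"position +{position} outside downstream flank")
            return self.downstream[idx]
        if position <= -1:
            idx = -position - 1
            if idx >= self.u_len:
                raise IndexError(f"position {position} outside upstream flank")
            return self.upstream[self.u_len - 1 - idx]
        raise IndexError("position 0 does not exist in the +1..+3 convention")


#: Sentinel for extensions that run off the transcript without a second stop.
ABSENT = None


@dataclass(frozen=True)
class ReadthroughExtension:
    """The region between the annotated stop and the next in-frame stop.

    ``peptide`` includes the readthrough-position residue as its first
    character (placeholder 'X' unless a residue was substituted);
    ``second_stop`` is ``None`` (ABSENT) when no downstream in-frame stop
    exists, in which case the transcript is excluded from PTS1 scoring.
    """

    ext_nt: str
    second_stop: Optional[str]
    peptide: str

    @property
    def bounded(self) -> bool:
        return self.second_stop is not None


def extract_scc(t: Transcript, u_len: int = 10, d_len: int = 10) -> StopCodonContext:
    """Extract the stop-codon context of ``t`` with the requested flank lengths.

    Flanks that extend past the transcript are truncated and flagged.
    Default flanks are 10 nt on each side.
    """
    if u_len < 0 or d_len < 0:
        raise ValueError("flank lengths must be non-negative")
    stop = t.stop_codon
    if stop not in STOP_CODONS and not t.is_control:
        raise ValueError(f"{t.id}: sense codon {stop!r} at stop position")
    up_start = t.stop_start - 1 - u_len
    truncated = False
    if up_start < 0:
        up_start = 0
        truncated = True
    upstream = t.seq[up_start : t.stop_start - 1]
    down_end = t.stop_start + 2 + d_len
    if down_end > len(t.seq):
        down_end = len(t.seq)
        truncated = True
    downstream = t.seq[t.stop_start + 2 : down_end]
    if truncated:
        warnings.warn(
            f"{t.id}: SCC flanks truncated to -{len(upstream)}/+{len(downstream)}",
            stacklevel=2,
        )
    return StopCodonContext(stop=stop, upstream=upstream, downstream=downstream, truncated=truncated)


def find_extension(t: Transcript, placeholder: str = READTHROUGH_PLACEHOLDER) -> ReadthroughExtension:
    """Scan codon-by-codon from +4 for the next in-frame stop.

    Returns the inter-stop nucleotide region (exclusive of the second stop)
    and its translation, prefixed with the readthrough-position residue.
    If no in-frame stop exists before the transcript end, ``second_stop``
    is ABSENT and ``ext_nt`` is the longest complete-codon prefix of the
    tail.
    """
    tail = t.seq[t.stop_start + 2 :]
    codons = []
    second_stop: Optional[str] = ABSENT
    for i in range(0, len(tail) - 2, 3):
        codon = tail[i : i + 3]
        if codon in STOP_CODONS:
            second_stop = codon
            break
        codons.append(codon)
    ext_nt = "".join(codons)
    peptide = placeholder + translate(ext_nt)
    return ReadthroughExtension(ext_nt=ext_nt, second_stop=second_stop, peptide=peptide)


def readthrough_construct_nt(t: Transcript, includes_second_stop: bool = True) -> str:
    """Nucleotides following the annotated stop that define a readthrough construct.

    With ``includes_second_stop=True`` (the default reading) the region runs
    from +4 through the second in-frame stop inclusive — e.g. 57 nt for an
    18-codon extension plus the second stop, encoding a 19-residue extended
    C-terminus once the readthrough residue is counted.
    """
    ext = find_extension(t)
    if not ext.bounded:
        raise ValueError(f"{t.id}: no downstream in-frame stop codon")
    if includes_second_stop:
        return ext.ext_nt + ext.second_stop
    return ext.ext_nt


# ---------------------------------------------------------------------------
# FASTA / sidecar I/O


def _stop_from_description(description: str) -> Optional[int]:
    for token in description.split():
        if token.startswith("stop="):
            return int(token.split("=", 1)[1])
    return None


def _token_from_description(description: str, key: str) -> Optional[str]:
    for token in description.split():
        if token.startswith(key + "="):
            return token.split("=", 1)[1]
    return None


def read_stop_table(path: str | Path) -> dict[str, int]:
    """Read a sidecar TSV of (id, stop_start) pairs; a header row is optional."""
    stops: dict[str, int] = {}
    with open(path, newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "id":
                continue
            stops[row[0]] = int(row[1])
    return stops


def read_transcripts(
    fasta: str | Path, stop_table: Optional[str | Path] = None
) -> list[Transcript]:
    """Load transcripts from FASTA.

    ``stop_start`` comes from the sidecar TSV when given, else from a
    ``stop=`` token in the FASTA header. Records marked ``control=1`` in
    the header are loaded as sense-codon controls.
    """
    stops = read_stop_table(stop_table) if stop_table else {}
    transcripts = []
    for record in SeqIO.parse(str(fasta), "fasta"):
        stop_start = stops.get(record.id)
        if stop_start is None:
            stop_start = _stop_from_description(record.description)
        if stop_start is None:
            raise ValueError(f"{record.id}: no stop_start (sidecar TSV or stop= header token)")
        species = _token_from_description(record.description, "species")
        is_control = _token_from_description(record.description, "control") == "1"
        transcripts.append(
            Transcript(
                id=record.id,
                seq=str(record.seq),
                stop_start=stop_start,
                species=species,
                is_control=is_control,
            )
        )
    return transcripts


def write_transcripts(transcripts: Iterable[Transcript], fasta: str | Path) -> None:
    """Write transcripts as FASTA with ``stop=`` (and ``species=``) header tokens."""
    with open(fasta, "w") as handle:
        for t in transcripts:
            tokens = [f"stop={t.stop_start}"]
            if t.species:
                tokens.append(f"species={t.species}")
            if t.is_control:
                tokens.append("control=1")
            handle.write(f">{t.id} {' '.join(tokens)}\n")
            for i in range(0, len(t.seq), 70):
                handle.write(t.seq[i : i + 70] + "\n")
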