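"""Mass-spectrometric identification of the readthrough-position residue.

The stop codon of a readthrough transcript can be decoded by different
near-cognate tRNAs, so the residue at the readthrough position is an
empirical question.  The strategy: build a variant proteoform database
with each of the 20 residues (plus a one-residue gap) at the readthrough
position, digest in silico with trypsin (one missed cleavage), and match
observed precursor and b/y fragment masses within ppm tolerances.

Two evidence tiers:

* relaxed — the precursor m/z of a readthrough-spanning tryptic peptide
  matches within the precursor tolerance;
* stringent — additionally at least one matched b- or y-ion on each side
  of the readthrough position, so the fragment series covers it.

Leucine and isoleucine are mass-identical and always reported as the
ambiguity label ``L/I``.  Intensities are carried through but never used
for identification.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from pyteomics import mgf as _mgf

# ---------------------------------------------------------------------------
# Mass table (versioned package data)

_MASS_DATA = json.loads(
    resources.files("readthrough.data").joinpath("monoisotopic_masses.json").read_text()
)
RESIDUE_MASS: dict[str, float] = _MASS_DATA["residues"]
WATER: float = _MASS_DATA["water"]
PROTON: float = _MASS_DATA["proton"]
MOD_DELTAS: dict[str, float] = {name: m["delta"] for name, m in _MASS_DATA["mods"].items()}
MOD_TARGETS: dict[str, str] = {name: m["target"] for name, m in _MASS_DATA["mods"].items()}

AMINO_ACIDS = tuple(sorted(RESIDUE_MASS))
GAP = "GAP"
MARKER = "X"


def residue_label(variant_label: str) -> str:
    """Collapse mass-identical Leu/Ile into one ambiguity label."""
    return "L/I" if variant_label in ("L", "I") else variant_label


# ---------------------------------------------------------------------------
# Variant proteoform database


@dataclass(frozen=True)
class VariantProteoformDB:
    """21 proteoforms differing only at the readthrough position.

    ``marker_pos`` is the 1-based position of the readthrough residue in
    the substitution variants; the GAP variant deletes that residue.
    """

    base_seq: str
    marker_pos: int
    variants: tuple[tuple[str, str], ...]  # (label, sequence)

    def sequence(self, label: str) -> str:
        for lab, seq in self.variants:
            if lab == label:
                return seq
        raise KeyError(label)


def build_variant_db(base_seq: str, marker: str = MARKER) -> VariantProteoformDB:
    """Expand a marked construct sequence into the 21-entry variant database.

    The marker must occur exactly once.  Variants are ordered alphabetically
    by residue with the one-residue GAP variant last.
    """
    base_seq = base_seq.upper()
    count = base_seq.count(marker)
    if count != 1:
        raise ValueError(f"expected exactly one marker {marker!r}, found {count}")
    idx = base_seq.index(marker)
    variants = [(aa, base_seq[:idx] + aa + base_seq[idx + 1 :]) for aa in AMINO_ACIDS]
    variants.append((GAP, base_seq[:idx] + base_seq[idx + 1 :]))
    return VariantProteoformDB(base_seq=base_seq, marker_pos=idx + 1, variants=tuple(variants))


# ---------------------------------------------------------------------------
# Tryptic digestion (Keil rule) and mass arithmetic


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with parent coordinates (1-based, inclusive)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    mods: tuple[tuple[int, str, float], ...] = ()  # (position in peptide, name, delta)

    @property
    def mono_mass(self) -> float:
        return peptide_mass(self.sequence, self.mods)

    def with_mods(self, mods: Sequence[tuple[int, str, float]]) -> "Peptide":
        return Peptide(self.sequence, self.start, self.end, self.missed_cleavages, tuple(mods))


def cleavage_sites(seq: str) -> list[int]:
    """Tryptic cut sites: after K/R except before P (Keil rule).

    A site ``i`` means cleavage between residues ``i`` and ``i+1``
    (1-based).
    """
    return [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in "KR" and seq[i] != "P"
    ]


def digest(seq: str, max_missed: int = 1) -> list[Peptide]:
    """In-silico tryptic digest with up to ``max_missed`` missed cleavages."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    unknown = set(seq) - set(RESIDUE_MASS)
    if unknown:
        raise ValueError(f"unknown residues in sequence: {sorted(unknown)}")
    sites = [0] + cleavage_sites(seq) + [len(seq)]
    peptides = []
    for i in range(len(sites) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(sites))):
            peptides.append(
                Peptide(
                    sequence=seq[sites[i] : sites[j]],
                    start=sites[i] + 1,
                    end=sites[j],
                    missed_cleavages=j - i - 1,
                )
            )
    return peptides


def peptide_mass(seq: str, mods: Sequence[tuple[int, str, float]] = ()) -> float:
    """Monoisotopic peptide mass: residues + water + modification deltas."""
    try:
        mass = sum(RESIDUE_MASS[aa] for aa in seq) + WATER
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return mass + sum(delta for _, _, delta in mods)


def mz(mass: float, charge: int) -> float:
    """m/z of a [M + zH]z+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * PROTON) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def variable_mod_combinations(
    seq: str, mod_names: Sequence[str]
) -> list[tuple[tuple[int, str, float], ...]]:
    """All subsets of variable-modification placements on a sequence."""
    sites = []
    for name in mod_names:
        target = MOD_TARGETS[name]
        delta = MOD_DELTAS[name]
        sites.extend((i + 1, name, delta) for i, aa in enumerate(seq) if aa == target)
    combos: list[tuple[tuple[int, str, float], ...]] = []
    for r in range(len(sites) + 1):
        combos.extend(itertools.combinations(sites, r))
    return combos


def fragment_ions(
    peptide: Peptide | str, series: Sequence[str] = ("b", "y"), charge: int = 1
) -> list[tuple[str, float]]:
    """Singly-B/y-style fragment ions (no neutral losses).

    b_i = prefix residue masses (+mods) + z protons, over z;
    y_i = suffix residue masses (+mods) + water + z protons, over z.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide, 1, len(peptide), 0)
    seq = peptide.sequence
    if len(seq) < 2:
        raise ValueError("fragmentation requires length >= 2")
    mod_at = {pos: delta for pos, _, delta in peptide.mods}
    res = [RESIDUE_MASS[aa] + mod_at.get(i + 1, 0.0) for i, aa in enumerate(seq)]
    ions = []
    prefix = 0.0
    suffix_totals = []
    total = sum(res)
    for i in range(1, len(seq)):
        prefix += res[i - 1]
        if "b" in series:
            ions.append((f"b{i}", (prefix + charge * PROTON) / charge))
        if "y" in series:
            suffix = total - prefix
            ions.append((f"y{len(seq) - i}", (suffix + WATER + charge * PROTON) / charge))
    return ions


# ---------------------------------------------------------------------------
# Peak lists and matching


@dataclass(frozen=True)
class PeakList:
    id: str
    precursor_mz: Optional[float]
    precursor_charge: Optional[int]
    fragments: tuple[tuple[float, float], ...] = ()  # (mz, intensity)


@dataclass(frozen=True)
class MSConfig:
    precursor_tol_ppm: float = 3.0
    xic_window_ppm: float = 20.0
    fragment_tol_ppm: float = 10.0
    mz_range: tuple[float, float] = (50.0, 2000.0)
    charges: tuple[int, ...] = (1, 2, 3)
    variable_mods: tuple[str, ...] = ("carbamidomethyl", "oxidation")
    enzyme: str = "trypsin"
    max_missed: int = 1

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class PeptideMatch:
    """Evidence record for one precursor match."""

    peaklist_id: str
    variant_label: str
    peptide: Peptide
    charge: int
    precursor_ppm: float
    matched_sites: tuple[int, ...]
    covers_readthrough: bool
    stringent: bool


@dataclass(frozen=True)
class IncorporationCall:
    """Aggregated residue call at one evidence tier."""

    residues: frozenset[str]
    tier: str  # "relaxed" | "stringent"
    evidence: tuple[PeptideMatch, ...]


def spanning_peptides(db: VariantProteoformDB, label: str, max_missed: int = 1) -> list[Peptide]:
    """Tryptic peptides of a variant that cover the readthrough position."""
    seq = db.sequence(label)
    peptides = digest(seq, max_missed=max_missed)
    p = db.marker_pos
    if label == GAP:
        # the deleted position leaves a junction between residues p-1 and p
        lo, hi = max(p - 1, 1), min(p, len(seq))
        return [pep for pep in peptides if pep.start <= lo and pep.end >= hi]
    return [pep for pep in peptides if pep.start <= p <= pep.end]


def _readthrough_covered(
    pep: Peptide, pos_in_peptide: int, matched_sites: set[int]
) -> bool:
    """Fragment coverage on each side of the readthrough position.

    Sites number the inter-residue bonds 1..len-1; the position is covered
    when a matched site exists at or left of position-1 and one at or right
    of the position.  A side that has no interior bond (position at a
    peptide terminus) is bounded by the precursor itself and is waived.
    """
    n = len(pep.sequence)
    left_ok = pos_in_peptide == 1 or any(s <= pos_in_peptide - 1 for s in matched_sites)
    right_ok = pos_in_peptide == n or any(s >= pos_in_peptide for s in matched_sites)
    return left_ok and right_ok


def match(
    peaklists: Sequence[PeakList],
    db: VariantProteoformDB,
    config: MSConfig = MSConfig(),
) -> list[IncorporationCall]:
    """Match peak lists against the variant database.

    Returns the two evidence-tier calls ``[stringent, relaxed]``; the
    stringent residue set is always a subset of the relaxed one.
    """
    evidence: list[PeptideMatch] = []
    for pl in peaklists:
        if pl.precursor_mz is None:
            warnings.warn(f"peak list {pl.id}: no precursor; skipped", stacklevel=2)
            continue
        for label, _seq in db.variants:
            for pep in spanning_peptides(db, label, config.max_missed):
                for mods in variable_mod_combinations(pep.sequence, config.variable_mods):
                    mass = peptide_mass(pep.sequence, mods)
                    charges = (
                        (pl.precursor_charge,)
                        if pl.precursor_charge
                        else config.charges
                    )
                    for z in charges:
                        if z not in config.charges:
                            continue
                        theo = mz(mass, z)
                        err = ppm_error(pl.precursor_mz, theo)
                        if abs(err) > config.precursor_tol_ppm:
                            continue
                        modded = pep.with_mods(mods)
                        sites = _matched_sites(modded, pl.fragments, config)
                        if label == GAP:
                            pos = max(db.marker_pos - pep.start, 1)
                        else:
                            pos = db.marker_pos - pep.start + 1
                        covered = _readthrough_covered(modded, pos, sites)
                        evidence.append(
                            PeptideMatch(
                                peaklist_id=pl.id,
                                variant_label=label,
                                peptide=modded,
                                charge=z,
                                precursor_ppm=err,
                                matched_sites=tuple(sorted(sites)),
                                covers_readthrough=covered,
                                stringent=covered and bool(sites),
                            )
                        )
    relaxed_residues = frozenset(residue_label(e.variant_label) for e in evidence)
    stringent_evidence = tuple(e for e in evidence if e.stringent)
    stringent_residues = frozenset(residue_label(e.variant_label) for e in stringent_evidence)
    return [
        IncorporationCall(residues=stringent_residues, tier="stringent", evidence=stringent_evidence),
        IncorporationCall(residues=relaxed_residues, tier="relaxed", evidence=tuple(evidence)),
    ]


def _matched_sites(
    pep: Peptide, fragments: Sequence[tuple[float, float]], config: MSConfig
) -> set[int]:
    """Inter-residue bonds supported by a matched b- or y-ion (charge 1)."""
    if not fragments or len(pep.sequence) < 2:
        return set()
    theo = fragment_ions(pep, series=("b", "y"), charge=1)
    n = len(pep.sequence)
    sites: set[int] = set()
    for label, t_mz in theo:
        if not (config.mz_range[0] <= t_mz <= config.mz_range[1]):
            continue
        for obs_mz, _intensity in fragments:
            if abs(ppm_error(obs_mz, t_mz)) <= config.fragment_tol_ppm:
                idx = int(label[1:])
                sites.add(idx if label[0] == "b" else n - idx)
                break
    return sites


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)


def write_mgf(peaklists: Sequence[PeakList], path: str | Path) -> None:
    spectra = []
    for pl in peaklists:
        params = {"title": pl.id}
        if pl.precursor_mz is not None:
            params["pepmass"] = pl.precursor_mz
        if pl.precursor_charge is not None:
            params["charge"] = pl.precursor_charge
        mzs = [f[0] for f in pl.fragments]
        intens = [f[1] for f in pl.fragments]
        spectra.append({"params": params, "m/z array": mzs, "intensity array": intens})
    _mgf.write(spectra, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[PeakList]:
    peaklists = []
    with _mgf.MGF(str(path)) as reader:
        for spectrum in reader:
            params = spectrum["params"]
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            charge = params.get("charge")
            charge_val = int(charge[0]) if charge else None
            frags = tuple(
                (float(m), float(i))
                for m, i in zip(spectrum["m/z array"], spectrum["intensity array"])
            )
            peaklists.append(
                PeakList(
                    id=params.get("title", ""),
                    precursor_mz=precursor,
                    precursor_charge=charge_val,
                    fragments=frags,
                )
            )
    return peaklists
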