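"""Seeded generators for every input the readthrough pipeline consumes.

Each generator draws from its own child stream of one global seed, so
modules can be tested independently and a fixed seed reproduces every
output byte-for-byte.  The defaults emulate the study conditions the
pipeline assumes: a transcript cohort with one planted high-readthrough
(consensus SCC) transcript carrying a PTS1-bearing extension among random
background CDS; dual-reporter plates with multiplicative log-normal noise
around true readthrough fractions; precursor+fragment peak lists for
readthrough-variant peptides with ppm-scale mass error; and orthologue
extension sets with mammalian CRL / non-mammalian SRL termini.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from readthrough import ms_ident
from readthrough.core_seq import CODON_TO_AA, STOP_CODONS, Transcript
from readthrough.conservation import MAMMAL, NON_MAMMAL, OTHER, OrthologueEntry, OrthologueSet
from readthrough.ms_ident import MSConfig, PeakList, VariantProteoformDB

#: codons per residue, alphabetical (deterministic reverse-translation order)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        AA_TO_CODONS.setdefault(_aa, []).append(_codon)

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")

#: Synthetic MDH1x-like defaults: consensus SCC, 19-residue extension
#: (readthrough placeholder first) ending in the mammalian CRL tripeptide.
DEFAULT_PLANTED_SCC = "UGACUAGAAGCAG"  # stop + 10 nt downstream
DEFAULT_PLANTED_EXTENSION = "XLEAEVAGNSQPTKLRCRL"

#: Synthetic myc-tagged construct C-terminal region with the readthrough
#: marker, used as the default variant-database base.
DEFAULT_MS_BASE_CONSTRUCT = "ASNVGSSKEVDLNXLEAEVAGNSQPTKLRCRLEQK"


@dataclass(frozen=True)
class TranscriptomeSpec:
    n_background: int = 99
    planted: tuple[tuple[str, str, Optional[str]], ...] = (
        ("planted_mdh1x_like", DEFAULT_PLANTED_SCC, DEFAULT_PLANTED_EXTENSION),
    )  # (id, stop+downstream, extension peptide or None)
    cds_codons: int = 40
    utr_len: int = 60


@dataclass(frozen=True)
class ReporterSpec:
    constructs: tuple[tuple[str, float], ...] = (("MDH1_SCC", 4.34), ("LDHB_SCC", 2.0))
    sigma: float = 0.1
    n_replicates: int = 5
    baseline: float = 1000.0
    control_ratio: float = 0.5
    control_name: str = "pDRVL"


@dataclass(frozen=True)
class MsSpec:
    variant_labels: tuple[str, ...] = ("W", "R")
    ppm_jitter: float = 1.0
    charges: tuple[tuple[str, int], ...] = (("W", 3), ("R", 2))
    default_charge: int = 2
    decoy_peaks: int = 20
    n_decoy_spectra: int = 0
    precursor_only: bool = False


@dataclass(frozen=True)
class OrthologueSpec:
    n_mammal: int = 6
    n_nonmammal: int = 5
    substitution_rate: float = 0.1
    include_other: bool = True
    mammal_template: str = "WLEPLKAASGNVQKTRCRL"
    nonmammal_template: str = "WLEPLKAASGNVQKTRSRL"
    other_template: str = "WLEPLKAASGNVQKTRARL"


@dataclass(frozen=True)
class SimSpec:
    seed: int = 0
    transcriptome: TranscriptomeSpec = field(default_factory=TranscriptomeSpec)
    reporter: ReporterSpec = field(default_factory=ReporterSpec)
    ms: MsSpec = field(default_factory=MsSpec)
    orthologues: OrthologueSpec = field(default_factory=OrthologueSpec)


def _rng(spec: SimSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


# ---------------------------------------------------------------------------
# Transcriptome


def reverse_translate(peptide: str, rng: np.random.Generator, prefix: str = "") -> str:
    """Pick codons for a peptide; the first codon must start with ``prefix``."""
    codons = []
    for i, aa in enumerate(peptide):
        if aa not in AA_TO_CODONS:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        options = AA_TO_CODONS[aa]
        if i == 0 and prefix:
            options = [c for c in options if c.startswith(prefix)]
            if not options:
                raise ValueError(
                    f"no codon for {aa!r} compatible with planted SCC prefix {prefix!r}"
                )
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _planted_tail(scc_downstream: str, ext_peptide: Optional[str], rng: np.random.Generator) -> str:
    """Build the 3' region from +4 so SCC and extension agree."""
    if ext_peptide is None:
        # unbounded: continue with sense codons only (no in-frame second stop)
        n_extra = 20
        extra = "".join(SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))] for _ in range(n_extra))
        return scc_downstream + extra

    residues = ext_peptide[1:]  # first char is the readthrough placeholder
    k, r = divmod(len(scc_downstream), 3)
    if k > len(residues):
        raise ValueError("planted SCC downstream longer than the extension it encodes")
    for i in range(k):
        codon = scc_downstream[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"planted SCC contains in-frame stop {codon} inside the extension")
        if CODON_TO_AA[codon] != residues[i]:
            raise ValueError(
                f"planted SCC codon {codon} encodes {CODON_TO_AA[codon]}, "
                f"extension expects {residues[i]}"
            )
    prefix = scc_downstream[3 * k :] if r else ""
    rest = reverse_translate(residues[k:], rng, prefix=prefix) if k < len(residues) else ""
    if prefix and not rest.startswith(prefix):
        raise AssertionError("codon prefix mismatch")
    ext_nt = scc_downstream[: 3 * k] + rest
    second_stop = ("UAA", "UAG", "UGA")[int(rng.integers(3))]
    utr = "".join("ACGU"[int(rng.integers(4))] for _ in range(12))
    return ext_nt + second_stop + utr


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))] for _ in range(n_codons))


def gen_transcriptome(spec: SimSpec) -> tuple[list[Transcript], dict]:
    """Random CDS background plus planted SCC/extension transcripts.

    Background stop contexts are resampled if they happen to match the
    planted consensus-like motif (stop + CUAG), so planted counts are exact
    ground truth.  Returns (transcripts, truth) where truth records planted
    ids and the planted SCC/extension strings.
    """
    tspec = spec.transcriptome
    rng = _rng(spec, 1)
    transcripts: list[Transcript] = []
    truth: dict = {"planted": {}, "background_ids": []}

    for tid, scc, ext_peptide in tspec.planted:
        stop, downstream = scc[:3], scc[3:]
        if stop not in STOP_CODONS:
            raise ValueError(f"{tid}: planted SCC must start with a stop codon, got {stop}")
        cds = _random_cds(tspec.cds_codons, rng)
        tail = _planted_tail(downstream, ext_peptide, rng)
        seq = cds + stop + tail
        transcripts.append(Transcript(id=tid, seq=seq, stop_start=len(cds) + 1))
        truth["planted"][tid] = {"scc": scc, "extension": ext_peptide}

    for i in range(tspec.n_background):
        tid = f"bg_{i:03d}"
        cds = _random_cds(tspec.cds_codons, rng)
        stop = ("UAA", "UAG", "UGA")[int(rng.integers(3))]
        while True:
            tail = "".join("ACGU"[int(rng.integers(4))] for _ in range(tspec.utr_len))
            if not (stop == "UGA" and tail.startswith("CUAG")):
                break
        transcripts.append(Transcript(id=tid, seq=cds + stop + tail, stop_start=len(cds) + 1))
        truth["background_ids"].append(tid)
    return transcripts, truth


# ---------------------------------------------------------------------------
# Reporter plates


def gen_reporter(spec: SimSpec) -> tuple[pd.DataFrame, dict]:
    """Dual-reporter plate with multiplicative log-normal noise.

    Per replicate: venus = baseline·e^N(0,σ²);
    hrluc = venus·(ρ/100)·control_ratio·e^N(0,σ²).  The 100% control
    construct is always included at ρ=100.
    """
    rspec = spec.reporter
    rng = _rng(spec, 2)
    rows = []
    constructs = ((rspec.control_name, 100.0),) + tuple(rspec.constructs)
    for name, rho in constructs:
        for rep in range(1, rspec.n_replicates + 1):
            venus = rspec.baseline * np.exp(rng.normal(0.0, rspec.sigma))
            hrluc = venus * (rho / 100.0) * rspec.control_ratio * np.exp(
                rng.normal(0.0, rspec.sigma)
            )
            rows.append(
                {
                    "construct": name,
                    "replicate": rep,
                    "venus": venus,
                    "hrluc": hrluc,
                    "blank_venus": 0.0,
                    "blank_hrluc": 0.0,
                }
            )
    truth = {name: rho for name, rho in constructs}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Peak lists


def default_variant_db() -> VariantProteoformDB:
    """Variant database for the packaged synthetic myc-tagged construct."""
    return ms_ident.build_variant_db(DEFAULT_MS_BASE_CONSTRUCT)


def _shortest_spanning(db: VariantProteoformDB, label: str) -> ms_ident.Peptide:
    peptides = ms_ident.spanning_peptides(db, label, max_missed=0)
    if not peptides:
        raise ValueError(f"variant {label}: no readthrough-spanning 0-missed peptide")
    return min(peptides, key=lambda p: len(p.sequence))


def gen_peaklists(
    spec: SimSpec, db: Optional[VariantProteoformDB] = None, config: MSConfig = MSConfig()
) -> tuple[list[PeakList], dict]:
    """Precursor + b/y-ladder peak lists for the requested variants.

    Every m/z gets relative Gaussian jitter of ``ppm_jitter`` ppm; uniform
    decoy fragment peaks are added, and optionally whole decoy spectra
    whose precursors match no database peptide.
    """
    db = db or default_variant_db()
    mspec = spec.ms
    rng = _rng(spec, 3)
    charge_map = dict(mspec.charges)
    peaklists = []
    truth: dict = {"variants": {}}

    def jitter(value: float) -> float:
        return value * (1.0 + rng.normal(0.0, mspec.ppm_jitter) * 1e-6)

    for label in mspec.variant_labels:
        pep = _shortest_spanning(db, label)
        z = charge_map.get(label, mspec.default_charge)
        precursor = jitter(ms_ident.mz(pep.mono_mass, z))
        fragments: list[tuple[float, float]] = []
        if not mspec.precursor_only:
            for _name, f_mz in ms_ident.fragment_ions(pep, series=("b", "y"), charge=1):
                if config.mz_range[0] <= f_mz <= config.mz_range[1]:
                    fragments.append((jitter(f_mz), float(rng.uniform(50.0, 100.0))))
        for _ in range(mspec.decoy_peaks):
            fragments.append(
                (float(rng.uniform(*config.mz_range)), float(rng.uniform(1.0, 10.0)))
            )
        fragments.sort()
        peaklists.append(
            PeakList(
                id=f"{label}_spanning",
                precursor_mz=precursor,
                precursor_charge=z,
                fragments=tuple(fragments),
            )
        )
        truth["variants"][label] = {"peptide": pep.sequence, "charge": z}

    all_mzs = [
        ms_ident.mz(ms_ident.peptide_mass(p.sequence, mods), z)
        for lab, _ in db.variants
        for p in ms_ident.spanning_peptides(db, lab, config.max_missed)
        for mods in ms_ident.variable_mod_combinations(p.sequence, config.variable_mods)
        for z in config.charges
    ]
    for i in range(mspec.n_decoy_spectra):
        while True:
            precursor = float(rng.uniform(*config.mz_range))
            if all(
                abs(ms_ident.ppm_error(precursor, m)) > 10 * config.precursor_tol_ppm
                for m in all_mzs
            ):
                break
        fragments = tuple(
            (float(rng.uniform(*config.mz_range)), float(rng.uniform(1.0, 10.0)))
            for _ in range(mspec.decoy_peaks)
        )
        peaklists.append(
            PeakList(
                id=f"decoy_{i:02d}",
                precursor_mz=precursor,
                precursor_charge=mspec.default_charge,
                fragments=fragments,
            )
        )
    return peaklists, truth


# ---------------------------------------------------------------------------
# Orthologues


def gen_orthologues(spec: SimSpec) -> tuple[OrthologueSet, dict]:
    """Clade-templated extension sets with per-site substitution noise.

    Sites outside the terminal tripeptide mutate independently with the
    configured rate; the terminal tripeptide (the PTS1) is never mutated.
    """
    ospec = spec.orthologues
    rng = _rng(spec, 4)
    aa = "ACDEFGHIKLMNPQRSTVWY"

    def mutate(template: str) -> str:
        chars = list(template)
        for i in range(len(chars) - 3):
            if rng.random() < ospec.substitution_rate:
                chars[i] = aa[int(rng.integers(len(aa)))]
        return "".join(chars)

    entries = []
    for i in range(ospec.n_mammal):
        entries.append(
            OrthologueEntry(f"mammal_{i:02d}", MAMMAL, mutate(ospec.mammal_template))
        )
    for i in range(ospec.n_nonmammal):
        entries.append(
            OrthologueEntry(f"nonmammal_{i:02d}", NON_MAMMAL, mutate(ospec.nonmammal_template))
        )
    if ospec.include_other:
        entries.append(OrthologueEntry("amphibian_00", OTHER, mutate(ospec.other_template)))
    oset = OrthologueSet(entries=tuple(entries))
    truth = {
        "templates": {
            MAMMAL: ospec.mammal_template,
            NON_MAMMAL: ospec.nonmammal_template,
        }
    }
    return oset, truth


# ---------------------------------------------------------------------------
# File output helpers


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def write_reporter_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_orthologues_fasta(oset: OrthologueSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for e in oset.entries:
            handle.write(f">{e.species} clade={e.clade}\n{e.extension}\n")
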