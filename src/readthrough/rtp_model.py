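"""Positional linear-regression readthrough-propensity (RTP) scoring.

The model regresses log10(readthrough %) on one-hot indicators of the
nucleotide identity at each modelled stop-relative position (the stop
triplet itself counts as one position with symbols UAA/UAG/UGA).  Per
position the coefficients are made identifiable with a sum-to-zero
constraint; the consensus motif is read off as the per-position
argmax-coefficient symbol over the maximal contiguous run of informative
positions starting at the stop codon.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from readthrough.core_seq import STOP_CODONS, StopCodonContext

NUCLEOTIDES = ("A", "C", "G", "U")
STOP_SYMBOLS = tuple(sorted(STOP_CODONS))

#: Default modelled positions: the stop triplet and the six 3' positions.
DEFAULT_POSITIONS = ("stop", "+4", "+5", "+6", "+7", "+8", "+9")

#: Optional upstream positions (off by default).
UPSTREAM_POSITIONS = ("-1", "-2", "-3", "-4", "-5", "-6")

#: Minimum per-position coefficient range (log10 units) for a position to
#: enter the consensus element.
DEFAULT_CONSENSUS_THRESHOLD = 0.2

RIDGE_LAMBDA = 1e-6


def position_symbols(position: str) -> tuple[str, ...]:
    return STOP_SYMBOLS if position == "stop" else NUCLEOTIDES


def _symbol_at(scc: StopCodonContext, position: str) -> str:
    if position == "stop":
        return scc.stop
    return scc.base_at(int(position))


def featurize(scc: StopCodonContext, positions: Sequence[str] = DEFAULT_POSITIONS) -> dict[tuple[str, str], int]:
    """One-hot encode an SCC over the modelled positions.

    Returns a mapping with exactly one active ``(position, symbol)``
    indicator per modelled position.  Raises if the SCC does not cover a
    modelled position.
    """
    active: dict[tuple[str, str], int] = {}
    for pos in positions:
        try:
            sym = _symbol_at(scc, pos)
        except IndexError as exc:
            raise ValueError(f"SCC does not cover modelled position {pos}: {exc}") from None
        if pos == "stop":
            if sym not in STOP_SYMBOLS:
                raise ValueError(f"sense codon {sym!r} at stop position")
        elif sym not in NUCLEOTIDES:
            raise ValueError(f"unexpected symbol {sym!r} at position {pos}")
        active[(pos, sym)] = 1
    return active


@dataclass(frozen=True)
class SCCMeasurement:
    """A dual-reporter readthrough measurement for one SCC (0-100 scale)."""

    scc: StopCodonContext
    readthrough_percent: float
    label: str = ""


@dataclass
class RTPModel:
    """Fitted RTP regression model.

    ``coef`` maps ``(position, symbol)`` to a weight; per position the
    weights over the observed symbols sum to zero (unobserved symbols carry
    weight 0).  The response scale is log10 of percent readthrough.
    """

    intercept: float
    positions: tuple[str, ...]
    coef: dict[tuple[str, str], float]
    scale: str = "log10_percent"
    residual_rmse: float = 0.0
    ridge_fallback: bool = False

    def score(self, scc: StopCodonContext) -> float:
        return score(self, scc)

    def coefficient_range(self, position: str) -> float:
        vals = [self.coef[(position, s)] for s in position_symbols(position)]
        return max(vals) - min(vals)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "positions": list(self.positions),
            "coef": [[pos, sym, w] for (pos, sym), w in sorted(self.coef.items())],
            "scale": self.scale,
            "residual_rmse": self.residual_rmse,
            "ridge_fallback": self.ridge_fallback,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RTPModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            intercept=payload["intercept"],
            positions=tuple(payload["positions"]),
            coef={(pos, sym): w for pos, sym, w in payload["coef"]},
            scale=payload["scale"],
            residual_rmse=payload.get("residual_rmse", 0.0),
            ridge_fallback=payload.get("ridge_fallback", False),
        )


def fit(
    measurements: Sequence[SCCMeasurement],
    positions: Sequence[str] = DEFAULT_POSITIONS,
) -> RTPModel:
    """Least-squares fit of log10(readthrough %) on positional indicators.

    Positions with fewer than two observed symbols in the data are
    uninformative and receive all-zero coefficients (their constant
    contribution is absorbed by the intercept).  A rank-deficient design
    among the informative columns falls back to a light ridge penalty
    (lambda=1e-6) with a warning.
    """
    if not measurements:
        raise ValueError("at least one measurement required")
    for m in measurements:
        if m.readthrough_percent <= 0:
            raise ValueError(
                f"non-positive readthrough value {m.readthrough_percent} ({m.label!r})"
            )
    y = np.log10([m.readthrough_percent for m in measurements])
    rows = [featurize(m.scc, positions) for m in measurements]

    observed: dict[str, list[str]] = {}
    for pos in positions:
        syms = sorted({s for row in rows for (p, s) in row if p == pos})
        observed[pos] = syms
    informative = [pos for pos in positions if len(observed[pos]) >= 2]

    columns = [(pos, sym) for pos in informative for sym in observed[pos]]
    X = np.zeros((len(rows), 1 + len(columns)))
    X[:, 0] = 1.0
    col_index = {c: j + 1 for j, c in enumerate(columns)}
    for i, row in enumerate(rows):
        for key in row:
            if key in col_index:
                X[i, col_index[key]] = 1.0

    # Structural rank: intercept + sum-to-zero dof per informative position.
    expected_rank = 1 + sum(len(observed[pos]) - 1 for pos in informative)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    ridge_fallback = False
    if rank < expected_rank:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {expected_rank}); "
            f"refitting with ridge lambda={RIDGE_LAMBDA}",
            stacklevel=2,
        )
        ridge_fallback = True
        penalty = np.sqrt(RIDGE_LAMBDA) * np.eye(X.shape[1])
        penalty[0, 0] = 0.0  # do not shrink the intercept
        X_aug = np.vstack([X, penalty])
        y_aug = np.concatenate([y, np.zeros(X.shape[1])])
        beta, _, _, _ = np.linalg.lstsq(X_aug, y_aug, rcond=None)

    intercept = float(beta[0])
    coef: dict[tuple[str, str], float] = {
        (pos, sym): 0.0 for pos in positions for sym in position_symbols(pos)
    }
    # Re-centre each informative position to sum-to-zero over its observed
    # symbols; the removed means move into the intercept (a pure
    # reparametrization, since every row activates exactly one symbol per
    # position).
    for pos in informative:
        vals = np.array([beta[col_index[(pos, s)]] for s in observed[pos]])
        centre = float(vals.mean())
        intercept += centre
        for s, v in zip(observed[pos], vals):
            coef[(pos, s)] = float(v - centre)

    fitted = X @ beta
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return RTPModel(
        intercept=intercept,
        positions=tuple(positions),
        coef=coef,
        residual_rmse=rmse,
        ridge_fallback=ridge_fallback,
    )


def score(model: RTPModel, scc: StopCodonContext) -> float:
    """RTP of an SCC: intercept plus one coefficient per modelled position."""
    active = featurize(scc, model.positions)
    return model.intercept + sum(model.coef[key] for key in active)


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus element extracted from a fitted model."""

    motif: str
    positions: tuple[str, ...]
    ranges: dict[str, float]
    tied_positions: tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.motif


def consensus(
    model: RTPModel, threshold: float = DEFAULT_CONSENSUS_THRESHOLD
) -> ConsensusResult:
    """Extract the high-readthrough consensus element.

    Per position the consensus symbol is the argmax coefficient (ties broken
    alphabetically and flagged).  The element is the maximal contiguous run
    of positions starting at the stop codon whose coefficient range is at
    least ``threshold`` (the stop triplet is always included and contributes
    its 3 nt).
    """
    downstream_order = [p for p in model.positions if p != "stop" and not p.startswith("-")]
    downstream_order.sort(key=int)
    motif_parts: list[str] = []
    used: list[str] = []
    ranges: dict[str, float] = {p: model.coefficient_range(p) for p in model.positions}
    tied: list[str] = []

    def argmax_symbol(pos: str) -> str:
        syms = position_symbols(pos)
        vals = [model.coef[(pos, s)] for s in syms]
        best = max(vals)
        winners = sorted(s for s, v in zip(syms, vals) if v == best)
        if len(winners) > 1:
            tied.append(pos)
        return winners[0]

    # The stop codon anchors the element.
    motif_parts.append(argmax_symbol("stop"))
    used.append("stop")
    for pos in downstream_order:
        if ranges[pos] >= threshold:
            motif_parts.append(argmax_symbol(pos))
            used.append(pos)
        else:
            break
    return ConsensusResult(
        motif="".join(motif_parts),
        positions=tuple(used),
        ranges=ranges,
        tied_positions=tuple(tied),
    )


# ---------------------------------------------------------------------------
# Packaged default model and comparison SCCs

#: The MDH1 wild-type stop-codon context (UGA followed by CUA G...).
MDH1_SCC = StopCodonContext(stop="UGA", upstream="AACGGCAUCG", downstream="CUAGAAGCAG")

#: Synthetic stand-in for a lower-readthrough LDHB-class SCC (off-consensus
#: downstream), used for ordering comparisons against MDH1.
LDHB_LIKE_SCC = StopCodonContext(stop="UGA", upstream="GCCAAGCUGA", downstream="GCUCAAGCAG")


def load_training_fixture() -> list[SCCMeasurement]:
    """The packaged wild-type/mutant SCC reporter measurement fixture."""
    text = resources.files("readthrough.data").joinpath("rtp_training.tsv").read_text()
    measurements = []
    reader = csv.DictReader(
        (line for line in text.splitlines() if line and not line.startswith("#")),
        delimiter="\t",
    )
    for row in reader:
        scc = StopCodonContext(
            stop=row["stop"], upstream="AACGGCAUCG", downstream=row["downstream"]
        )
        measurements.append(
            SCCMeasurement(
                scc=scc,
                readthrough_percent=float(row["readthrough_percent"]),
                label=row["label"],
            )
        )
    return measurements


@lru_cache(maxsize=1)
def default_model() -> RTPModel:
    """Default RTP model fitted to the packaged reporter-measurement fixture."""
    return fit(load_training_fixture())


def score_table(
    model: RTPModel, sccs: Iterable[tuple[str, StopCodonContext]]
) -> list[tuple[str, float]]:
    """Score a cohort of (id, SCC) pairs; convenience for TSV export."""
    return [(tid, score(model, scc)) for tid, scc in sccs]
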