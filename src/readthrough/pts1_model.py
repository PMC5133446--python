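"""Scoring of candidate peroxisomal targeting signals (PTS1) at C-termini.

A PTS1 is a C-terminal signal centred on the terminal tripeptide
(canonically SKL) with weaker contributions from the preceding context.
The model here is a transparent logistic log-odds scorer: a position
weight matrix over the last three residues (-3, -2, -1) plus per-position
residue-class weights over context positions -12..-4, trained by
penalized maximum likelihood on a packaged fixture of PTS1-class and
non-PTS1 termini.  The raw score maps to a probability through the
logistic function; a terminus is called functional when its probability
reaches the model's stored threshold.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from readthrough.core_seq import ReadthroughExtension

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
TRIPEPTIDE_POSITIONS = (-3, -2, -1)
CONTEXT_POSITIONS = tuple(range(-12, -3))  # -12..-4

#: Physicochemical classes used for the context positions.
RESIDUE_CLASSES = {
    "basic": set("KRH"),
    "acidic": set("DE"),
    "hydrophobic": set("FILVWYM"),
    "polar_small": set("ACGNPQST"),
}
CLASS_NAMES = tuple(RESIDUE_CLASSES)


def residue_class(aa: str) -> Optional[str]:
    for name, members in RESIDUE_CLASSES.items():
        if aa in members:
            return name
    return None


@dataclass(frozen=True)
class PTS1Score:
    """Score of one C-terminus: raw log-odds, probability, functional call."""

    raw: float
    probability: float
    functional: bool
    flags: tuple[str, ...] = ()


@dataclass
class PTS1Model:
    """Terminal-tripeptide PWM + context-class log-odds model."""

    tripeptide_pwm: dict[tuple[int, str], float]
    context_weights: dict[tuple[int, str], float]
    bias: float
    threshold: float

    def min_weight(self, position: int) -> float:
        return min(self.tripeptide_pwm[(position, aa)] for aa in AMINO_ACIDS)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tripeptide_pwm": [[p, aa, w] for (p, aa), w in sorted(self.tripeptide_pwm.items())],
            "context_weights": [[p, c, w] for (p, c), w in sorted(self.context_weights.items())],
            "bias": self.bias,
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PTS1Model":
        payload = json.loads(Path(path).read_text())
        return cls(
            tripeptide_pwm={(p, aa): w for p, aa, w in payload["tripeptide_pwm"]},
            context_weights={(p, c): w for p, c, w in payload["context_weights"]},
            bias=payload["bias"],
            threshold=payload["threshold"],
        )


def _logistic(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def score_pts1(model: PTS1Model, cterm: str) -> PTS1Score:
    """Score a C-terminal peptide for PTS1 function.

    Only the last 12 residues matter (last 3 through the PWM, -12..-4
    through class weights; missing context positions contribute 0).  A
    placeholder 'X' in the last three positions is scored with the minimum
    PWM weight for that position and flagged.
    """
    cterm = cterm.upper()
    if len(cterm) < 3:
        raise ValueError("PTS1 scoring requires at least 3 residues")
    flags: list[str] = []
    raw = model.bias
    for pos in TRIPEPTIDE_POSITIONS:
        aa = cterm[pos]
        if aa == "X":
            raw += model.min_weight(pos)
            flags.append(f"placeholder_at_{pos}")
        elif aa in set(AMINO_ACIDS):
            raw += model.tripeptide_pwm[(pos, aa)]
        else:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
    for pos in CONTEXT_POSITIONS:
        if len(cterm) < -pos:
            continue
        cls = residue_class(cterm[pos])
        if cls is not None:
            raw += model.context_weights[(pos, cls)]
    probability = _logistic(raw)
    functional = probability >= _logistic(model.threshold)
    return PTS1Score(raw=raw, probability=probability, functional=functional, flags=tuple(flags))


def score_extension(
    model: PTS1Model, ext: ReadthroughExtension, parent_cterm: str = ""
) -> PTS1Score:
    """Score the C-terminus exposed by readthrough.

    The scored sequence is the parent protein C-terminus concatenated with
    the extension peptide (readthrough residue first).  Unbounded
    extensions (ABSENT second stop) cannot expose a defined C-terminus and
    raise.
    """
    if not ext.bounded:
        raise ValueError("extension has no downstream in-frame stop (ABSENT); cannot score PTS1")
    full = parent_cterm + ext.peptide
    return score_pts1(model, full)


# ---------------------------------------------------------------------------
# Training


def _features(terminus: str) -> np.ndarray:
    vec = np.zeros(len(TRIPEPTIDE_POSITIONS) * len(AMINO_ACIDS) + len(CONTEXT_POSITIONS) * len(CLASS_NAMES))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for j, pos in enumerate(TRIPEPTIDE_POSITIONS):
        aa = terminus[pos]
        if aa in aa_index:
            vec[j * len(AMINO_ACIDS) + aa_index[aa]] = 1.0
    base = len(TRIPEPTIDE_POSITIONS) * len(AMINO_ACIDS)
    for j, pos in enumerate(CONTEXT_POSITIONS):
        if len(terminus) < -pos:
            continue
        cls = residue_class(terminus[pos])
        if cls is not None:
            vec[base + j * len(CLASS_NAMES) + CLASS_NAMES.index(cls)] = 1.0
    return vec


def fit(
    termini: Sequence[str], labels: Sequence[int], C: float = 1.0
) -> PTS1Model:
    """Fit the PWM/context model by L2-penalized logistic regression.

    The functional threshold is the midpoint between the lowest positive
    and the highest negative raw score on the training data; if the classes
    are not linearly separated the threshold falls back to 0 (probability
    0.5).
    """
    X = np.vstack([_features(t) for t in termini])
    y = np.asarray(labels, dtype=int)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    w = clf.coef_[0]
    bias = float(clf.intercept_[0])
    pwm = {}
    for j, pos in enumerate(TRIPEPTIDE_POSITIONS):
        for i, aa in enumerate(AMINO_ACIDS):
            pwm[(pos, aa)] = float(w[j * len(AMINO_ACIDS) + i])
    base = len(TRIPEPTIDE_POSITIONS) * len(AMINO_ACIDS)
    ctx = {}
    for j, pos in enumerate(CONTEXT_POSITIONS):
        for k, cls in enumerate(CLASS_NAMES):
            ctx[(pos, cls)] = float(w[base + j * len(CLASS_NAMES) + k])
    raw_scores = X @ w + bias
    pos_min = float(raw_scores[y == 1].min())
    neg_max = float(raw_scores[y == 0].max())
    threshold = (pos_min + neg_max) / 2.0 if pos_min > neg_max else 0.0
    return PTS1Model(tripeptide_pwm=pwm, context_weights=ctx, bias=bias, threshold=threshold)


def load_training_fixture() -> tuple[list[str], list[int], list[str]]:
    """Packaged (terminus, label, id) training fixture."""
    text = resources.files("readthrough.data").joinpath("pts1_termini.tsv").read_text()
    termini, labels, ids = [], [], []
    reader = csv.DictReader(
        (line for line in text.splitlines() if line and not line.startswith("#")),
        delimiter="\t",
    )
    for row in reader:
        ids.append(row["id"])
        termini.append(row["terminus"])
        labels.append(int(row["label"]))
    return termini, labels, ids


@lru_cache(maxsize=1)
def default_model() -> PTS1Model:
    """Default PTS1 model trained on the packaged termini fixture."""
    termini, labels, _ = load_training_fixture()
    return fit(termini, labels)
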