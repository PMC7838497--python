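"""Condition epochs and drug-effect time courses.

An experiment is a sequence of labelled epochs — a baseline (``control``)
period, a ``drug`` superfusion period, and a post-washout (``wash``) period.
Drug effects on quantal release are modelled as multiplicative factors on
event rate and amplitude that approach their asymptote exponentially after
drug onset (bath-applied drugs reach cells at depth with variable delay) and
are retained at a configurable fraction after washout, reflecting the
long-lasting potentiation seen with nicotinic agonists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

CONDITIONS = ("control", "drug", "wash")


@dataclass(frozen=True)
class Epoch:
    label: str
    start: float  # s
    end: float  # s

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.label not in CONDITIONS:
            raise ValueError(f"epoch label must be one of {CONDITIONS}, got {self.label!r}")
        if not (self.end > self.start >= 0):
            raise ValueError(f"epoch must satisfy 0 <= start < end, got [{self.start}, {self.end}]")


@dataclass
class DrugProtocol:
    """Ordered condition epochs plus the drug-effect parameters.

    Parameters
    ----------
    epochs
        Non-overlapping, strictly increasing ``(label, start, end)`` epochs
        in seconds. Exactly one ``control`` epoch must precede any ``drug``
        epoch.
    drug_rate_ratio
        Asymptotic multiplicative effect of the drug on event rate
        (dimensionless, > 0). Default 2.72 — a +172% frequency increase,
        typical of bath nicotine on spontaneous glutamate release.
    drug_amp_ratio
        Asymptotic multiplicative effect on event amplitude. Default 2.40
        (+140% amplitude increase).
    onset_tau
        Time constant (s) of the exponential approach to the asymptotic
        effect after drug onset. Default 60 s.
    washout_persistence
        Fraction in [0, 1] of the drug effect retained during wash epochs.
        1 models effects that persist for the whole post-washout recording;
        0 models full reversal.
    """

    epochs: list[Epoch]
    drug_rate_ratio: float = 2.72
    drug_amp_ratio: float = 2.40
    onset_tau: float = 60.0
    washout_persistence: float = 1.0

    def __post_init__(self) -> None:
        self.epochs = [e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs]
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        for prev, cur in zip(self.epochs, self.epochs[1:]):
            if cur.start < prev.end:
                raise ValueError("epochs must be non-overlapping and strictly increasing")
        labels = [e.label for e in self.epochs]
        if "drug" in labels:
            first_drug = labels.index("drug")
            if "control" not in labels[:first_drug]:
                raise ValueError("a control epoch must precede any drug epoch")
        if labels.count("control") != 1:
            raise ValueError("exactly one control epoch is required")
        if self.drug_rate_ratio <= 0 or self.drug_amp_ratio <= 0:
            raise ValueError("drug ratios must be > 0")
        if self.onset_tau <= 0:
            raise ValueError("onset_tau must be > 0")
        if not (0.0 <= self.washout_persistence <= 1.0):
            raise ValueError("washout_persistence must lie in [0, 1]")

    # -- epoch lookups ----------------------------------------------------

    @property
    def start(self) -> float:
        return self.epochs[0].start

    @property
    def end(self) -> float:
        return self.epochs[-1].end

    @property
    def control(self) -> Epoch:
        return next(e for e in self.epochs if e.label == "control")

    @property
    def drug_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.label == "drug"]

    @property
    def drug_onset(self) -> float:
        de = self.drug_epochs
        if not de:
            raise ValueError("protocol has no drug epoch")
        return de[0].start

    def label_at(self, t: float) -> str | None:
        """Condition label at time ``t`` (None in gaps / outside epochs)."""
        for e in self.epochs:
            if e.start <= t < e.end:
                return e.label
        if self.epochs and t == self.end:
            return self.epochs[-1].label
        return None

    def condition_of_frame(self, n_frames: int, frame_rate: float) -> list[str | None]:
        """Condition label of each imaging frame (frame-centre convention)."""
        centres = (np.arange(n_frames) + 0.5) / frame_rate
        return [self.label_at(float(t)) for t in centres]

    # -- drug-effect time course ------------------------------------------

    def effect_factor(self, t: np.ndarray, ratio: float) -> np.ndarray:
        """Multiplicative drug-effect factor at times ``t`` for an asymptotic ratio.

        Control epochs sit at 1. During a drug epoch the factor approaches
        ``ratio`` exponentially with ``onset_tau``. Wash epochs hold
        ``1 + washout_persistence * (level_at_washout - 1)``. Gaps hold the
        running level.
        """
        t = np.asarray(t, dtype=float)
        out = np.ones_like(t)
        level = 1.0  # factor carried across epoch boundaries
        for e in self.epochs:
            m = (t >= e.start) & (t < e.end)
            if e.label == "control":
                level = 1.0
                out[m] = 1.0
            elif e.label == "drug":
                vals = ratio + (level - ratio) * np.exp(-(t[m] - e.start) / self.onset_tau)
                out[m] = vals
                level = ratio + (level - ratio) * np.exp(-e.duration / self.onset_tau)
            else:  # wash
                level = 1.0 + self.washout_persistence * (level - 1.0)
                out[m] = level
        out[t >= self.end] = level
        return out

    def rate_factor(self, t: np.ndarray) -> np.ndarray:
        return self.effect_factor(t, self.drug_rate_ratio)

    def amp_factor(self, t: np.ndarray) -> np.ndarray:
        return self.effect_factor(t, self.drug_amp_ratio)


def three_stage_protocol(
    control: float = 600.0,
    drug: float = 600.0,
    wash: float = 600.0,
    **kwargs,
) -> DrugProtocol:
    """Convenience constructor: contiguous control / drug / wash protocol."""
    epochs = [
        Epoch("control", 0.0, control),
        Epoch("drug", control, control + drug),
        Epoch("wash", control + drug, control + drug + wash),
    ]
    return DrugProtocol(epochs=epochs, **kwargs)


def control_only_protocol(duration: float = 360.0) -> DrugProtocol:
    """A single baseline epoch (e.g. one 6-min imaging video)."""
    return DrugProtocol(epochs=[Epoch("control", 0.0, duration)])
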