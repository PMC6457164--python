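"""Two-phase verification sampling and design weights.

Phase 1 screens everyone; phase 2 invites every screen-positive woman and a
random fraction (1 in k) of screen-negatives for the gold-standard interview.
Verification bias from this stratified selection is corrected by design
weights w_h = N_h / n_h -- the stratum frame count over the realized
interviewed count -- so consent non-response is absorbed into the weight, as
in the source study (weights 906/287 for screen-positives and 9057/258 for
screen-negatives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SamplingError

STRATA = ("positive", "negative")


@dataclass(frozen=True)
class DesignWeights:
    """Design weight for one screening stratum: w = N_h / n_h."""

    stratum: str
    frame_count: int
    interviewed_count: int

    def __post_init__(self) -> None:
        if self.interviewed_count < 1:
            raise SamplingError(
                f"stratum {self.stratum!r} has no interviewed women; "
                "design weight undefined")
        if self.frame_count < self.interviewed_count:
            raise SamplingError(
                f"stratum {self.stratum!r}: interviewed count "
                f"{self.interviewed_count} exceeds frame count {self.frame_count}")

    @property
    def weight(self) -> float:
        return self.frame_count / self.interviewed_count


def draw_sample(
    population: pd.DataFrame,
    negative_fraction_schedule: list[tuple[int, int]],
    seed: int,
) -> pd.DataFrame:
    """Apply the two-phase selection and return a copy with selection flags.

    ``negative_fraction_schedule`` is a list of ``(start_index, k)`` pairs:
    from enrolment position ``start_index`` onwards screen-negatives are
    independently selected with probability 1/k (1:k sampling).  The first
    entry must start at 0.  Screen-positives are always invited.  Interviewed
    means invited and consented.
    """
    if len(population) == 0:
        raise SamplingError("population is empty")
    if not negative_fraction_schedule:
        raise SamplingError("negative_fraction_schedule is empty")
    starts = [s for s, _ in negative_fraction_schedule]
    if starts[0] != 0:
        raise SamplingError("schedule must start at enrolment index 0")
    if starts != sorted(starts):
        raise SamplingError("schedule start indices must be increasing")
    for _, k in negative_fraction_schedule:
        if k < 1:
            raise SamplingError(f"sampling ratio 1:{k} invalid; k must be >= 1")

    rng = np.random.default_rng(seed)
    n = len(population)
    prob = np.empty(n)
    bounds = starts + [n]
    for (start, k), end in zip(negative_fraction_schedule, bounds[1:]):
        prob[start:end] = 1.0 / k

    out = population.copy()
    positive = (out["stratum"] == "positive").to_numpy()
    invited = positive | (rng.random(n) < prob)
    out["invited"] = invited.astype(int)
    out["interviewed"] = (invited & out["consented"].to_numpy().astype(bool)).astype(int)
    return out


def frame_totals(population: pd.DataFrame) -> dict[str, int]:
    """Stratum sizes of the sampling frame (everyone screened)."""
    counts = population["stratum"].value_counts()
    return {h: int(counts.get(h, 0)) for h in STRATA}


def compute_weights(
    sample: pd.DataFrame,
    frame: dict[str, int],
) -> dict[str, DesignWeights]:
    """Design weights per stratum from realized interviewed counts.

    ``frame`` maps stratum -> N_h (frame count).  Raises
    :class:`SamplingError` naming the stratum if it has no interviewed women.
    """
    interviewed = sample[sample["interviewed"] == 1]
    weights: dict[str, DesignWeights] = {}
    for stratum, n_frame in frame.items():
        n_int = int((interviewed["stratum"] == stratum).sum())
        if n_int == 0:
            raise SamplingError(f"stratum {stratum!r} has no interviewed women")
        weights[stratum] = DesignWeights(stratum, n_frame, n_int)
    return weights


def attach_weights(
    sample: pd.DataFrame,
    weights: dict[str, DesignWeights],
) -> pd.DataFrame:
    """Return a copy with a ``design_weight`` column (NaN for non-interviewed)."""
    out = sample.copy()
    w = out["stratum"].map({h: dw.weight for h, dw in weights.items()})
    out["design_weight"] = np.where(out["interviewed"] == 1, w, np.nan)
    return out


def two_phase_sample(
    population: pd.DataFrame,
    negative_fraction_schedule: list[tuple[int, int]],
    seed: int,
) -> tuple[pd.DataFrame, dict[str, DesignWeights]]:
    """Convenience wrapper: draw, weight and attach in one call."""
    sampled = draw_sample(population, negative_fraction_schedule, seed)
    weights = compute_weights(sampled, frame_totals(population))
    return attach_weights(sampled, weights), weights
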