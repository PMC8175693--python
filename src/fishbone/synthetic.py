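"""Synthetic pairwise-choice psychophysics data.

No raw participant data is deposited for the indentation-judgment
experiment, so the analysis stage is exercised end-to-end with choices
simulated from a Thurstonian latent-scale model: each stimulus evokes a
noisy internal magnitude (a normal discriminal process centred on its latent
scale value) and the larger draw wins the trial.  The bundled profiles mimic
the qualitative shape of the reported judgments: perceived indentation peaks
at a 0.4 mm rib interval and decays for wide intervals, with sharp dips at
the 1.0 and 2.0 mm intervals where pins move coherently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psychophysics import PairwiseChoiceTable

__all__ = [
    "LatentScaleProfile",
    "PROFILE_TEMPLATES",
    "generate_profile",
    "generate_choices",
]

_INTERVALS: tuple[float, ...] = (0.2, 0.4, 1.0, 1.4, 1.8, 2.0, 2.2, 3.0, 4.0)

#: Latent indentation magnitudes per rib interval (arbitrary units).
PROFILE_TEMPLATES: dict[str, tuple[float, ...]] = {
    # Peak at 0.4 mm, monotone decay beyond 1.4 mm.
    "unimodal": (-0.6, 1.2, 1.0, 0.8, 0.5, 0.4, 0.3, -0.1, -0.5),
    # Same, with the coherent-stimulus dips at 1.0 and 2.0 mm.
    "unimodal_with_dips": (-0.6, 1.2, -0.2, 0.8, 0.5, -0.4, 0.3, -0.1, -0.5),
    "flat": (0.0,) * 9,
}


@dataclass(frozen=True)
class LatentScaleProfile:
    """Latent perceived-indentation magnitude per rib interval."""

    intervals: tuple[float, ...]
    values: np.ndarray
    condition: str = "PM1"
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.values):
            raise ValueError("one latent value per rib interval required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent values must be finite")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.intervals), name=self.condition)


def generate_profile(
    template: str,
    condition: str = "PM1",
    values=None,
    intervals: tuple[float, ...] = _INTERVALS,
    dispersion: float = 1.0,
) -> LatentScaleProfile:
    """Build a latent-scale profile from a named template.

    Templates: ``unimodal``, ``unimodal_with_dips``, ``flat``, or ``custom``
    (which passes ``values`` through unchanged).
    """
    if template == "custom":
        if values is None:
            raise ValueError("custom template requires explicit values")
        vals = np.asarray(values, dtype=float)
    elif template in PROFILE_TEMPLATES:
        if intervals != _INTERVALS:
            raise ValueError("named templates are defined over the experimental intervals")
        vals = np.asarray(PROFILE_TEMPLATES[template], dtype=float)
    else:
        raise ValueError(
            f"unknown template {template!r}; known: {sorted(PROFILE_TEMPLATES) + ['custom']}"
        )
    return LatentScaleProfile(
        intervals=tuple(intervals), values=vals, condition=condition,
        dispersion=dispersion,
    )


def generate_choices(
    profile: LatentScaleProfile,
    n_participants: int = 12,
    trials_per_pair: int = 4,
    seed: int = 0,
    return_trials: bool = False,
):
    """Simulate 2AFC indentation judgments under the Case V choice model.

    For every trial of every unordered pair ``(i, j)`` two independent
    normal discriminal processes are drawn around the latent scale values
    (common dispersion), and the stimulus with the larger draw is recorded
    as chosen.  The expected proportion choosing ``i`` over ``j`` is
    therefore ``Phi((s_i - s_j) / (sqrt(2) * dispersion))``.

    Returns the pooled :class:`PairwiseChoiceTable`, and with
    ``return_trials`` also the tidy trial table (columns ``participant_id``,
    ``interval_a_mm``, ``interval_b_mm``, ``chosen_mm``).
    """
    if trials_per_pair < 1:
        raise ValueError("trials_per_pair must be >= 1")
    rng = np.random.default_rng(seed)
    labels = profile.intervals
    n = len(labels)
    wins = np.zeros((n, n), dtype=int)
    trial_rows = []
    for participant in range(n_participants):
        for i in range(n):
            for j in range(i + 1, n):
                draws_i = rng.normal(profile.values[i], profile.dispersion, trials_per_pair)
                draws_j = rng.normal(profile.values[j], profile.dispersion, trials_per_pair)
                i_won = draws_i > draws_j
                wins[i, j] += int(i_won.sum())
                wins[j, i] += int((~i_won).sum())
                if return_trials:
                    for won in i_won:
                        trial_rows.append(
                            (
                                participant,
                                labels[i],
                                labels[j],
                                labels[i] if won else labels[j],
                            )
                        )
    table = PairwiseChoiceTable(labels=labels, wins=wins)
    if return_trials:
        trials = pd.DataFrame(
            trial_rows,
            columns=["participant_id", "interval_a_mm", "interval_b_mm", "chosen_mm"],
        )
        return table, trials
    return table
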