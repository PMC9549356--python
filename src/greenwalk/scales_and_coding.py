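"""Scoring of the short mood scale and coding of social-interaction intensity.

The six diary items are semantic differentials on a 1–6 scale, two per
affect dimension (valence: unwell–well, discontent–content; calmness:
relaxed–tense, calm–agitated; energetic arousal: tired–awake, without
energy–full of energy).  The calmness anchors run from the calm pole on the
left, so those two items are reverse-keyed (7 − raw) before averaging; a
higher processed score then always means a more positive / calmer / more
energized state.  Social-interaction intensity is a four-level ordinal code
reconstructed from three branching prompt questions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DIMENSIONS = ("valence", "calmness", "energetic_arousal")

#: raw item columns, two per dimension, in storage order
ITEM_COLUMNS = {
    "valence": ["val_unwell_well", "val_discontent_content"],
    "calmness": ["calm_relaxed_tense", "calm_calm_agitated"],
    "energetic_arousal": ["ea_tired_awake", "ea_noenergy_energy"],
}
ALL_ITEM_COLUMNS = [c for cols in ITEM_COLUMNS.values() for c in cols]


@dataclass(frozen=True)
class AffectScores:
    valence: float
    calmness: float
    energetic_arousal: float


@dataclass(frozen=True)
class SocialContextAnswers:
    """Answers to the three branching prompt questions.

    A — walking alone or with a known person ("alone" / "with_known");
    B — other people in sight (only asked when alone);
    C — interacted with someone, e.g. greeting (only asked when B is yes).
    """

    a: str
    b: bool | None = None
    c: bool | None = None

    def __post_init__(self) -> None:
        if self.a not in ("alone", "with_known"):
            raise ValueError(f"invalid answer A: {self.a!r}")
        if self.a == "with_known":
            if self.b is not None or self.c is not None:
                raise ValueError("B/C are only asked when walking alone")
        else:
            if self.b is None:
                raise ValueError("B is required when walking alone")
            if self.b is False and self.c is not None:
                raise ValueError("C is only asked when B is yes")
            if self.b is True and self.c is None:
                raise ValueError("C is required when B is yes")


def _check_items(values, lo=1.0, hi=6.0) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(arr < lo) or np.any(arr > hi) or not np.all(np.isfinite(arr)):
        raise ValueError(f"item responses must lie in [{lo}, {hi}]")
    return arr


def score_affect(record, reverse_key_calmness: bool = True) -> AffectScores:
    """Score one diary record (mapping of item column → response).

    Each dimension is the mean of its two items; the calmness items are
    reverse-keyed first unless ``reverse_key_calmness`` is disabled (for
    data already stored with the calm pole on the high end).
    """
    out = {}
    for dim, cols in ITEM_COLUMNS.items():
        items = _check_items([record[c] for c in cols])
        if dim == "calmness" and reverse_key_calmness:
            items = 7.0 - items
        out[dim] = float(items.mean())
    return AffectScores(**out)


def score_table(df: pd.DataFrame, reverse_key_calmness: bool = True) -> pd.DataFrame:
    """Vectorized :func:`score_affect` over a raw diary table."""
    out = df.copy()
    for dim, cols in ITEM_COLUMNS.items():
        items = _check_items(df[cols].to_numpy())
        if dim == "calmness" and reverse_key_calmness:
            items = 7.0 - items
        out[dim] = items.mean(axis=1)
    return out


def cronbach_alpha(items) -> float | None:
    """Cronbach's alpha of a two-item scale on pooled (aggregated) data.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(item sum)),
    with k = 2.  Returns None when the total variance is zero (undefined).
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a 2-column item table")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return None
    item_var = arr.var(axis=0, ddof=1).sum()
    return float(2.0 * (1.0 - item_var / total_var))


def code_si_intensity(ans: SocialContextAnswers) -> int:
    """Four-level social-interaction intensity from the A/B/C answers.

    1 walking alone, nobody around; 2 alone but others in sight; 3 brief
    interaction (e.g. greeting someone); 4 walking together with a known
    person.
    """
    if ans.a == "with_known":
        return 4
    if not ans.b:
        return 1
    return 3 if ans.c else 2


def si_to_answers(intensity: int) -> SocialContextAnswers:
    """Inverse of :func:`code_si_intensity` (used by the simulator)."""
    if intensity == 4:
        return SocialContextAnswers("with_known")
    if intensity == 1:
        return SocialContextAnswers("alone", b=False)
    if intensity == 2:
        return SocialContextAnswers("alone", b=True, c=False)
    if intensity == 3:
        return SocialContextAnswers("alone", b=True, c=True)
    raise ValueError(f"si_intensity must be 1..4, got {intensity}")


def dummy_code_si(intensity: int) -> tuple[int, int, int]:
    """Dummies (D1, D2, D3) with intensity 1 as the reference category."""
    if intensity not in (1, 2, 3, 4):
        raise ValueError(f"si_intensity must be 1..4, got {intensity}")
    return (int(intensity == 2), int(intensity == 3), int(intensity == 4))


def add_si_dummies(df: pd.DataFrame, col: str = "si_intensity") -> pd.DataFrame:
    out = df.copy()
    si = df[col].to_numpy()
    if not np.isin(si, [1, 2, 3, 4]).all():
        raise ValueError("si_intensity values must be in 1..4")
    for k, name in ((2, "D1"), (3, "D2"), (4, "D3")):
        out[name] = (si == k).astype(float)
    return out


def calibrate_item_noise(latent_var: float, target_alpha: float,
                         latent_mean: float = 4.8,
                         integer_items: bool = False,
                         seed: int = 0, n: int = 200_000) -> float:
    """Item-noise variance that yields a target Cronbach's alpha.

    With two parallel items (item = latent + noise), alpha = 2v/(2v + w)
    where v is the pooled latent variance and w the per-item noise
    variance, so w = 2v(1 - alpha)/alpha in the continuous case.  When
    responses are clipped to [1, 6] and rounded to integers the closed form
    no longer holds and w is found by bisection on a large simulated
    sample (deterministic for a fixed seed).
    """
    if not 0 < target_alpha < 1:
        raise ValueError("target alpha must be in (0, 1)")
    if latent_var <= 0:
        raise ValueError("latent variance must be > 0")
    w_cont = 2.0 * latent_var * (1.0 - target_alpha) / target_alpha
    if not integer_items:
        return w_cont

    rng = np.random.default_rng(seed)
    latent = rng.normal(latent_mean, np.sqrt(latent_var), n)
    eps = rng.standard_normal((n, 2))

    def alpha_at(w: float) -> float:
        items = latent[:, None] + np.sqrt(w) * eps
        items = np.clip(np.rint(items), 1, 6)
        return cronbach_alpha(items) or 0.0

    lo, hi = 0.0, 4.0 * latent_var
    if alpha_at(lo) < target_alpha:
        return 0.0  # discretization alone already lowers alpha below target
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if alpha_at(mid) > target_alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
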