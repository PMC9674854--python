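"""GC skew and replication-origin prediction.

On a bidirectionally replicating replicon the leading strand is typically
G-enriched, so the windowed GC skew (G-C)/(G+C) changes sign at the origin
and terminus and the cumulative skew is V-shaped with its minimum at the
origin and maximum at the terminus (for the G-rich-leading convention used
here; flip ``origin_at_minimum`` for the opposite convention).

For circular replicons the cumulative series is de-trended by subtracting
the linear ramp of the total skew, which makes the extrema invariant to the
(arbitrary) rotation of the assembled sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 10


@dataclass
class SkewProfile:
    """Windowed and cumulative GC skew along a replicon."""

    window: int
    step: int
    length: int
    circular: bool
    positions: np.ndarray  # window centers, bp (mod length when circular)
    skew: np.ndarray  # per-window (G-C)/(G+C)
    cumulative: np.ndarray = field(init=False)
    origin_pos: int | None = None
    terminus_pos: int | None = None
    signal_strength: float = 0.0

    def __post_init__(self) -> None:
        self.cumulative = np.cumsum(self.skew)

    @property
    def n_windows(self) -> int:
        return len(self.skew)

    def detrended(self) -> np.ndarray:
        """Cumulative skew minus the linear ramp of the total (circular only)."""
        cum = self.cumulative
        if not self.circular or len(cum) == 0:
            return cum
        n = len(cum)
        ramp = cum[-1] * (np.arange(1, n + 1) / n)
        return cum - ramp


def gc_skew(window_seq: str) -> float:
    """(nG - nC) / (nG + nC); 0 when the window has no G or C."""
    seq = window_seq.upper()
    g = seq.count("G")
    c = seq.count("C")
    if g + c == 0:
        return 0.0
    return (g - c) / (g + c)


def windowed_skew(
    seq: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    circular: bool = True,
) -> SkewProfile:
    """Compute GC skew in sliding windows at offsets 0, step, 2*step, ...

    Circular sequences wrap so every position is covered; on linear input the
    window must not exceed the sequence length.
    """
    length = len(seq)
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if window > length:
        raise ValueError(f"window {window} exceeds sequence length {length}")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    if circular:
        offsets = np.arange(0, length, step)
        is_g = np.concatenate([is_g, is_g[:window]])
        is_c = np.concatenate([is_c, is_c[:window]])
    else:
        offsets = np.arange(0, length - window + 1, step)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    g = cg[offsets + window] - cg[offsets]
    c = cc[offsets + window] - cc[offsets]
    denom = g + c
    skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    positions = (offsets + window / 2.0) % length if circular else offsets + window / 2.0
    return SkewProfile(
        window=window,
        step=step,
        length=length,
        circular=circular,
        positions=positions.astype(float),
        skew=skew.astype(float),
    )


def predict_origin_terminus(
    profile: SkewProfile, origin_at_minimum: bool = True
) -> tuple[int | None, int | None, float]:
    """Locate origin/terminus at the extrema of the (de-trended) cumulative skew.

    Returns ``(origin_pos, terminus_pos, signal_strength)`` and records them
    on the profile. With the default convention the origin sits at the global
    minimum (leading strand G-rich). All-zero skew yields undefined extrema
    and strength 0.
    """
    if profile.n_windows < 4:
        raise ValueError("need at least 4 windows to predict extrema")
    det = profile.detrended()
    if not np.any(profile.skew):
        profile.origin_pos = None
        profile.terminus_pos = None
        profile.signal_strength = 0.0
        return None, None, 0.0
    i_min = int(np.argmin(det))
    i_max = int(np.argmax(det))
    if not origin_at_minimum:
        i_min, i_max = i_max, i_min
    origin = int(round(profile.positions[i_min])) % profile.length
    terminus = int(round(profile.positions[i_max])) % profile.length
    strength = float(det.max() - det.min())
    profile.origin_pos = origin
    profile.terminus_pos = terminus
    profile.signal_strength = strength
    return origin, terminus, strength


def _subsampled(profile: SkewProfile) -> np.ndarray:
    """Non-overlapping window skews (stride window/step), for null calibration."""
    stride = max(1, profile.window // profile.step)
    return profile.skew[::stride]


def _strength(series: np.ndarray, circular: bool) -> float:
    cum = np.cumsum(series)
    if circular and len(cum):
        n = len(cum)
        cum = cum - cum[-1] * (np.arange(1, n + 1) / n)
    return float(cum.max() - cum.min()) if len(cum) else 0.0


def permutation_threshold(
    profile: SkewProfile,
    n_permutations: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Signal-strength threshold from permuted (exchangeable) window skews.

    Permutation is applied to the non-overlapping subseries so the null is
    exchangeable despite the overlapping default windows.
    """
    sub = _subsampled(profile)
    rng = np.random.default_rng(seed)
    null = np.array(
        [_strength(rng.permutation(sub), profile.circular) for _ in range(n_permutations)]
    )
    return float(np.quantile(null, quantile))


def v_shape_agreement(profile: SkewProfile) -> float:
    """Fraction of windows whose skew sign matches a two-replichore split.

    The de-trended cumulative of the non-overlapping subseries defines the
    candidate origin (minimum) and terminus (maximum); skew is expected
    positive on the origin->terminus arm and negative on the return arm.
    Zero-skew windows are ignored.
    """
    sub = _subsampled(profile)
    n = len(sub)
    if n < 4:
        return 0.0
    cum = np.cumsum(sub)
    if profile.circular:
        cum = cum - cum[-1] * (np.arange(1, n + 1) / n)
    i_min, i_max = int(np.argmin(cum)), int(np.argmax(cum))
    idx = np.arange(n)
    if i_min <= i_max:
        ascending = (idx > i_min) & (idx <= i_max)
    else:
        ascending = (idx > i_min) | (idx <= i_max)
    expected = np.where(ascending, 1.0, -1.0)
    nonzero = sub != 0
    if not nonzero.any():
        return 0.0
    return float(np.mean(np.sign(sub[nonzero]) == expected[nonzero]))


def classify_bidirectional(
    profile: SkewProfile,
    min_strength: float | None = None,
    min_agreement: float = 0.75,
    seed: int = 0,
) -> str:
    """Classify the replication signal as ``supported``, ``weak`` or ``none``.

    ``supported``: strength above threshold and a clean V-shaped (two-arm)
    sign pattern; ``weak``: strength above threshold but a noisy sign
    pattern; ``none``: strength below the (permutation-null) threshold.
    """
    sub = _subsampled(profile)
    strength = _strength(sub, profile.circular)
    if min_strength is None:
        min_strength = permutation_threshold(profile, seed=seed)
    if strength < min_strength or not np.any(sub):
        return "none"
    if v_shape_agreement(profile) >= min_agreement:
        return "supported"
    return "weak"
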