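"""Outlier removal and normalization of raw reactivity profiles.

Two normalization methods are supported, one per project:

* ``simple`` (boxplot-style, recommended below ~300 nt): the top 2% of valid
  reactivities are outliers (set to the sentinel), the next 8% are averaged
  into the normalization factor, and every remaining value is divided by it.
* ``interquartile`` (for longer molecules): values above Q3 + 1.5*IQR are
  outliers; the factor is the mean of the top 10% of the remaining values.

Negative-value rules are applied last, i.e. on the normalized scale: values in
[-0.3, 0) are clamped to zero, values below -0.3 become undetermined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .formats_io import SENTINEL, ReactivityProfile, is_valid


class NormalizationError(ValueError):
    """Raised when a normalization factor cannot be computed."""


@dataclass(frozen=True)
class NormalizationConfig:
    method: str = "simple"
    simple_outlier_fraction: float = 0.02
    simple_norm_fraction: float = 0.08
    iqr_multiplier: float = 1.5
    iqr_norm_fraction: float = 0.10
    zero_floor: float = -0.3
    length_guideline: int = 300

    def __post_init__(self) -> None:
        if self.method not in {"simple", "interquartile"}:
            raise ValueError(f"unknown normalization method {self.method!r}")
        for name in ("simple_outlier_fraction", "simple_norm_fraction", "iqr_norm_fraction"):
            frac = getattr(self, name)
            if not 0 < frac < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def _ranked_valid_indices(values: np.ndarray) -> np.ndarray:
    """Indices of valid positions sorted by descending value.

    Ties are broken by position index (lower index first) so that cutoffs are
    deterministic.
    """
    idx = np.flatnonzero(is_valid(values))
    order = np.lexsort((idx, -values[idx]))
    return idx[order]


def normalize_simple(profile: ReactivityProfile, cfg: NormalizationConfig | None = None) -> ReactivityProfile:
    """Boxplot-style normalization: drop top 2%, scale by mean of next 8%."""
    cfg = cfg or NormalizationConfig()
    values = profile.values.copy()
    ranked = _ranked_valid_indices(values)
    n_valid = ranked.size
    if n_valid == 0:
        raise NormalizationError("profile has no valid reactivity values")
    n_out = math.ceil(cfg.simple_outlier_fraction * n_valid)
    n_ref = math.ceil(cfg.simple_norm_fraction * n_valid)
    outliers = ranked[:n_out]
    reference = ranked[n_out:n_out + n_ref]
    if reference.size == 0:
        raise NormalizationError("too few valid values to build a reference set")
    factor = float(np.mean(values[reference]))
    if factor <= 0:
        raise NormalizationError("normalization factor nonpositive")
    keep = ranked[n_out:]
    values[keep] = values[keep] / factor
    values[outliers] = SENTINEL
    return profile.copy_with(values)


def normalize_interquartile(profile: ReactivityProfile, cfg: NormalizationConfig | None = None) -> ReactivityProfile:
    """IQR-based normalization: drop values above Q3 + 1.5*IQR, scale by the
    mean of the top 10% of what remains.

    Quartiles use linear interpolation (numpy's default, the common "type 7"
    convention).
    """
    cfg = cfg or NormalizationConfig(method="interquartile")
    values = profile.values.copy()
    valid_idx = np.flatnonzero(is_valid(values))
    if valid_idx.size < 4:
        raise NormalizationError("interquartile method needs at least 4 valid values")
    valid_vals = values[valid_idx]
    q1, q3 = np.percentile(valid_vals, [25, 75])
    cutoff = q3 + cfg.iqr_multiplier * (q3 - q1)
    outliers = valid_idx[valid_vals > cutoff]
    remaining = valid_idx[valid_vals <= cutoff]
    if remaining.size == 0:
        raise NormalizationError("all values flagged as outliers")
    rem_vals = values[remaining]
    order = np.lexsort((remaining, -rem_vals))
    n_ref = math.ceil(cfg.iqr_norm_fraction * remaining.size)
    reference = remaining[order[:n_ref]]
    factor = float(np.mean(values[reference]))
    if factor <= 0:
        raise NormalizationError("normalization factor nonpositive")
    values[remaining] = values[remaining] / factor
    values[outliers] = SENTINEL
    return profile.copy_with(values)


def apply_negative_rules(profile: ReactivityProfile, cfg: NormalizationConfig | None = None) -> ReactivityProfile:
    """Clamp mildly negative values to zero; mark strongly negative ones
    undetermined."""
    cfg = cfg or NormalizationConfig()
    values = profile.values.copy()
    valid = is_valid(values)
    clamp = valid & (values >= cfg.zero_floor) & (values < 0)
    drop = valid & (values < cfg.zero_floor)
    values[clamp] = 0.0
    values[drop] = SENTINEL
    return profile.copy_with(values)


def preprocess_profile(profile: ReactivityProfile, cfg: NormalizationConfig | None = None) -> ReactivityProfile:
    """Full preprocessing: outlier removal + normalization, then the
    negative-value rules (applied on the normalized scale).

    Sentinel positions are excluded from every percentile / average
    computation and propagate unchanged.
    """
    cfg = cfg or NormalizationConfig()
    if cfg.method == "simple":
        if profile.length > cfg.length_guideline:
            warnings.warn(
                f"'simple' normalization is recommended for molecules shorter than "
                f"{cfg.length_guideline} nt (profile has {profile.length}); "
                "consider the 'interquartile' method",
                stacklevel=2,
            )
        normalized = normalize_simple(profile, cfg)
    else:
        normalized = normalize_interquartile(profile, cfg)
    return apply_negative_rules(normalized, cfg)
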