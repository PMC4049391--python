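"""Per-variant transcript quantification from gel band densitometry.

A lane of a stained gel carries the ClaI-type digest of a mixture of
paralogous amplicons.  With an intercalating dye the signal of a band is
proportional to DNA *mass*, i.e. (molar amount) x (fragment length in bp).
Given the band/variant incidence structure predicted by
:mod:`capskit.restriction`, per-lane band intensities are converted into
per-variant molar abundances, normalized to a loading-control amplicon,
and compared across conditions with pairwise t-tests under Bonferroni
correction.

Two quantification modes are offered:

``diagnostic``
    each variant is read off its own diagnostic band(s) only — intensity
    divided by fragment length (mass -> molar), averaged over the variant's
    diagnostic bands.  Shared bands are ignored, mirroring manual gel
    densitometry practice.
``least_squares``
    all bands, shared ones included, enter a nonnegative least-squares
    solve of  intensity ≈ M · abundance,  where M is the mass incidence
    matrix.  Strictly more information, at the price of trusting the
    linear mass model for every band.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ComputationError, ValidationError
from .restriction import BandTable, SequenceVariant


@dataclass
class IncidenceMatrix:
    """Band-class x variant matrix of per-transcript mass contributions.

    ``matrix.loc[band, v]`` is the summed length (bp) of variant ``v``'s
    fragments that co-migrate in that band class — the mass that one molar
    unit of transcript ``v`` deposits in the band.  Column sums equal the
    variant full lengths (every base ends up in exactly one band).
    """

    matrix: pd.DataFrame  # index: representative band length, columns: variant ids
    diagnostic: pd.Series  # bool per band row

    @property
    def band_lengths(self) -> np.ndarray:
        return self.matrix.index.to_numpy(dtype=float)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class LaneDensitometry:
    """One gel lane: band intensities plus the loading-control intensity."""

    lane_id: str
    condition: str
    bands: list[tuple[float, float]]  # (band length class, intensity >= 0)
    reference_intensity: float

    def __post_init__(self) -> None:
        if self.reference_intensity <= 0:
            raise ValidationError(
                f"lane {self.lane_id!r}: reference intensity must be > 0"
            )
        for length, intensity in self.bands:
            if intensity < 0:
                raise ValidationError(
                    f"lane {self.lane_id!r}: negative intensity at band {length}"
                )


@dataclass
class VariantAbundance:
    variant: str
    raw: float  # molar signal before normalization
    normalized: float  # raw / reference intensity
    percent_change: float | None = None
    se: float | None = None


def build_incidence(
    bands: BandTable, variants: Sequence[SequenceVariant]
) -> IncidenceMatrix:
    """Assemble the mass incidence matrix from a band table.

    Raises if the band table's variants do not match the supplied variant
    set, or if any variant's fragments fail to sum to its length.
    """
    variant_ids = [v.id for v in variants]
    lengths = {v.id: v.length for v in variants}
    band_variants = set().union(*(c.variants for c in bands.classes))
    if band_variants != set(variant_ids):
        raise ValidationError(
            f"band table variants {sorted(band_variants)} do not match "
            f"supplied variants {sorted(variant_ids)}"
        )
    rows = []
    diag = []
    index = []
    for cls in bands.classes:
        row = {vid: 0.0 for vid in variant_ids}
        for vid, frag_len in cls.members:
            row[vid] += frag_len
        rows.append(row)
        diag.append(cls.diagnostic)
        index.append(cls.representative_length)
    matrix = pd.DataFrame(rows, index=pd.Index(index, name="band_length"))
    matrix = matrix[variant_ids]
    for vid in variant_ids:
        total = matrix[vid].sum()
        if total != lengths[vid]:
            raise ValidationError(
                f"variant {vid!r}: incidence column sums to {total}, "
                f"expected full length {lengths[vid]}"
            )
    return IncidenceMatrix(matrix=matrix, diagnostic=pd.Series(diag, index=matrix.index))


def _match_bands(
    lane: LaneDensitometry, incidence: IncidenceMatrix, tolerance: float
) -> np.ndarray:
    """Vector of intensities aligned to incidence rows (unmatched rows -> 0)."""
    ref_lengths = incidence.band_lengths
    y = np.zeros(len(ref_lengths))
    for length, intensity in lane.bands:
        rel = np.abs(ref_lengths - length) / ((ref_lengths + length) / 2.0)
        idx = int(np.argmin(rel))
        if rel[idx] > tolerance:
            raise ValidationError(
                f"lane {lane.lane_id!r}: band of {length} bp matches no "
                f"predicted band class within tolerance {tolerance}"
            )
        y[idx] += intensity
    return y


def quantify(
    lane: LaneDensitometry,
    incidence: IncidenceMatrix,
    mode: str = "diagnostic",
    tolerance: float = 0.02,
) -> list[VariantAbundance]:
    """Convert one lane's band intensities into per-variant abundances.

    Returns reference-normalized molar abundances in the order of the
    incidence matrix columns.  See the module docstring for the two modes.
    """
    if mode not in ("diagnostic", "least_squares"):
        raise ValidationError(f"unknown quantification mode {mode!r}")
    y = _match_bands(lane, incidence, tolerance)
    M = incidence.matrix.to_numpy(dtype=float)
    variant_ids = incidence.variant_ids
    if not np.any(y > 0):
        warnings.warn(
            f"lane {lane.lane_id!r}: all band intensities are zero", stacklevel=2
        )
        return [VariantAbundance(v, 0.0, 0.0) for v in variant_ids]
    if mode == "diagnostic":
        raw = np.empty(len(variant_ids))
        diag_mask = incidence.diagnostic.to_numpy()
        for j, vid in enumerate(variant_ids):
            rows = np.flatnonzero(diag_mask & (M[:, j] > 0))
            if rows.size == 0:
                raise ValidationError(
                    f"variant {vid!r} has no diagnostic band; use least_squares mode"
                )
            raw[j] = float(np.mean(y[rows] / M[rows, j]))
    else:
        raw, _ = optimize.nnls(M, y)
    normalized = raw / lane.reference_intensity
    return [
        VariantAbundance(v, float(r), float(n))
        for v, r, n in zip(variant_ids, raw, normalized)
    ]


def percent_change(treated: float, control: float) -> float:
    """Percent change of a treated abundance versus control: 100·(T/C − 1)."""
    if control == 0:
        raise ValidationError("percent_change undefined for control == 0")
    return 100.0 * (treated / control - 1.0)


@dataclass
class GroupComparison:
    """Result of all pairwise two-sample t-tests across conditions."""

    table: pd.DataFrame  # group1, group2, t, p, significant
    letters: dict[str, str]
    alpha: float
    adjusted_alpha: float
    n_comparisons: int


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> GroupComparison:
    """Pairwise Student's t-tests with Bonferroni-adjusted significance.

    ``groups`` maps condition label -> replicate values (per-biological-
    replicate means; average technical replicates before calling this).
    With ``correction='bonferroni'`` the per-comparison threshold is
    alpha/m over the m = g(g−1)/2 pairwise comparisons.  Conditions that
    share a significance letter are not significantly different
    (insert-and-absorb compact letter display).
    """
    names = list(groups)
    if any(len(groups[g]) < 2 for g in names):
        raise ValidationError("compare_groups: every group needs >= 2 replicates")
    if correction not in ("bonferroni", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    adjusted = alpha / m if (correction == "bonferroni" and m > 0) else alpha
    records = []
    sig_pairs = []
    for g1, g2 in pairs:
        a = np.asarray(groups[g1], dtype=float)
        b = np.asarray(groups[g2], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance groups give nan
            t, p = stats.ttest_ind(a, b)
        significant = bool(np.isfinite(p) and p < adjusted)
        if significant:
            sig_pairs.append((g1, g2))
        records.append(
            {"group1": g1, "group2": g2, "t": float(t), "p": float(p),
             "significant": significant}
        )
    letters = _letter_display(names, sig_pairs)
    return GroupComparison(
        table=pd.DataFrame.from_records(records),
        letters=letters,
        alpha=alpha,
        adjusted_alpha=adjusted,
        n_comparisons=m,
    )


def _letter_display(names: list[str], sig_pairs: list[tuple[str, str]]) -> dict[str, str]:
    # insert-and-absorb: split every letter set containing a significant pair
    letter_sets: list[set[str]] = [set(names)]
    for g1, g2 in sig_pairs:
        for s in [s for s in letter_sets if g1 in s and g2 in s]:
            letter_sets.remove(s)
            for reduced in (s - {g1}, s - {g2}):
                if reduced and not any(reduced <= other for other in letter_sets):
                    letter_sets.append(reduced)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # stable ordering: by first member's position in `names`
    letter_sets.sort(key=lambda s: min(names.index(g) for g in s))
    out = {g: "" for g in names}
    for letter, s in zip(alphabet, letter_sets):
        for g in names:
            if g in s:
                out[g] += letter
    return out


def summarize_conditions(
    abundances: Mapping[str, Mapping[str, Sequence[float]]],
    control: str,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-variant condition summary: mean, SE, percent change vs control.

    ``abundances[condition][variant]`` holds replicate normalized
    abundances.  One t-test family (all pairwise condition contrasts) is
    run per variant.
    """
    conditions = list(abundances)
    if control not in conditions:
        raise ValidationError(f"control condition {control!r} not present")
    variants = list(next(iter(abundances.values())))
    rows = []
    for variant in variants:
        groups = {cond: abundances[cond][variant] for cond in conditions}
        comp = compare_groups(groups, alpha=alpha, correction=correction)
        ctrl_mean = float(np.mean(groups[control]))
        for cond in conditions:
            vals = np.asarray(groups[cond], dtype=float)
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
            rows.append(
                {
                    "condition": cond,
                    "variant": variant,
                    "normalized": mean,
                    "se": se,
                    "percent_change": percent_change(mean, ctrl_mean)
                    if ctrl_mean > 0
                    else np.nan,
                    "letter": comp.letters[cond],
                }
            )
    return pd.DataFrame.from_records(rows)
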