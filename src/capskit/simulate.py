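"""Synthetic data generators: paralog sets, growth curves, gel lanes.

Every generator is seed-deterministic and, run noise-free, is an exact
forward model of the corresponding estimator, so the estimators applied
to their own generator's output recover the generating parameters to
numerical precision.  Defaults reproduce the motivating assay:

* a trio of near-identical paralogous ORFs with a ClaI site polymorphism
  (a: 1968 bp, no site, carrying a 9-bp insertion just after the start
  codon; b: 1959 bp, one cut 1752 bp downstream of the start codon;
  c: 1959 bp, cuts at 1098 and 1752 bp);
* yeast growth curves whose exponential rate is Michaelis–Menten-limited
  by external sulfate (ladder 0–100 µM, hourly A600 readings over 25 h,
  starting OD 0.1, six replicates);
* stained-gel band intensities under the mass model (intensity ∝ molar
  amount × fragment length) with multiplicative log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ComputationError, ConfigError
from .gelquant import IncidenceMatrix, LaneDensitometry
from .growth import LN2, GrowthCurve
from .restriction import CLAI, EnzymeSpec, SequenceVariant, find_cut_sites


@dataclass(frozen=True)
class VariantEdit:
    """How one variant differs from the common backbone."""

    cut_coords: tuple[int, ...] = ()
    insert_5prime: int = 0  # bases inserted immediately after the start codon


@dataclass
class ParalogSpec:
    """Recipe for a paralog set with controlled cut-site geometry."""

    base_length: int = 1959
    variants: dict[str, VariantEdit] = field(
        default_factory=lambda: {
            "a": VariantEdit(cut_coords=(), insert_5prime=9),
            "b": VariantEdit(cut_coords=(1752,)),
            "c": VariantEdit(cut_coords=(1098, 1752)),
        }
    )
    enzyme: EnzymeSpec = CLAI
    seed: int = 0


DEFAULT_PARALOG_SPEC = ParalogSpec()


def _strip_motif(seq: np.ndarray, enzyme: EnzymeSpec, rng, protected=()) -> None:
    """Mutate the sequence in place until the motif no longer occurs.

    ``protected`` lists half-open (start, stop) 0-based intervals that must
    not be touched (implanted sites); a motif occurrence overlapping a
    protected interval is unresolvable and raises.
    """
    bases = np.array(list("ACGT"))
    m = len(enzyme.recognition)
    for _ in range(100):
        text = "".join(seq)
        occurrences = [
            i for i in range(len(text) - m + 1) if text[i : i + m] == enzyme.recognition
        ]
        spurious = [
            i
            for i in occurrences
            if not any(i >= start and i + m <= stop for start, stop in protected)
        ]
        if not spurious:
            return
        for i in spurious:
            mutable = [
                j
                for j in range(i, i + m)
                if not any(start <= j < stop for start, stop in protected)
            ]
            if not mutable:
                raise ConfigError(
                    "infeasible paralog spec: a spurious recognition site lies "
                    "entirely inside implanted ones and cannot be removed"
                )
            j = mutable[len(mutable) // 2]
            seq[j] = rng.choice(bases[bases != seq[j]])
    raise ComputationError("failed to purge recognition motif after 100 rounds")


def make_paralog_set(spec: ParalogSpec = DEFAULT_PARALOG_SPEC) -> list[SequenceVariant]:
    """Generate a paralog set with exactly the requested cut sites.

    All variants share one random backbone (they are near-identical
    paralogs); the recognition motif is implanted so each requested cut
    coordinate is realized under the convention c = p + cut_offset − 1,
    and a 5' insertion of the requested size is placed immediately after
    the leading ATG.  Generated sequences are rescanned: each variant
    contains the motif exactly as many times as it has cuts.
    """
    enzyme = spec.enzyme
    m = len(enzyme.recognition)
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    backbone = rng.choice(bases, size=spec.base_length)
    backbone[:3] = list("ATG")  # start-codon analog
    _strip_motif(backbone, enzyme, rng)

    variants = []
    for vid, edit in spec.variants.items():
        seq = backbone.copy()
        protected = []
        for c in edit.cut_coords:
            p = c - enzyme.cut_offset + 1  # 1-based motif start
            if p < 1 or p + m - 1 > spec.base_length:
                raise ConfigError(
                    f"variant {vid!r}: cut at {c} puts the motif outside the sequence"
                )
            start = p - 1
            if any(start < stop and start + m > s for s, stop in protected):
                raise ConfigError(
                    f"variant {vid!r}: overlapping motif placements for cuts "
                    f"{edit.cut_coords}"
                )
            seq[start : start + m] = list(enzyme.recognition)
            protected.append((start, start + m))
        _strip_motif(seq, enzyme, rng, protected=protected)
        if edit.insert_5prime:
            insert = rng.choice(bases, size=edit.insert_5prime)
            seq = np.concatenate([seq[:3], insert, seq[3:]])
            _strip_motif(seq, enzyme, rng,
                         protected=[(s + edit.insert_5prime, e + edit.insert_5prime)
                                    for s, e in protected])
        variant = SequenceVariant(vid, "".join(seq))
        observed = find_cut_sites(variant, enzyme).cut_coords
        shift = edit.insert_5prime
        expected = tuple(sorted(c + shift for c in edit.cut_coords))
        if observed != expected:
            raise ComputationError(
                f"variant {vid!r}: generated cut sites {observed} do not match "
                f"requested {expected}"
            )
        variants.append(variant)
    return variants


@dataclass
class GrowthSimConfig:
    """Mechanistic growth simulation: uptake-limited exponential growth.

    The realized exponential rate at external substrate concentration S is
    k(S) = ln 2 · k_max·S/(k_G_true + S); OD follows A0·e^(k·t) (or
    logistic growth with the same initial rate when ``plateau_od`` is set)
    times per-observation multiplicative log-normal noise of log-sd
    ``noise_sd``.
    """

    k_max: float = 0.5  # dt^-1 h^-1 (doubling time 2 h at saturation)
    k_G_true: float = 5.46  # µM
    concentrations: tuple[float, ...] = (0.0, 1.0, 2.5, 5.0, 7.5, 10.0, 25.0, 50.0, 100.0)
    times: tuple[float, ...] = tuple(float(t) for t in range(26))  # 0..25 h hourly
    A0: float = 0.1
    noise_sd: float = 0.02
    replicates: int = 6
    seed: int = 0
    plateau_od: float | None = None

    def __post_init__(self) -> None:
        if self.k_max <= 0 or self.k_G_true <= 0 or self.A0 <= 0:
            raise ConfigError("k_max, k_G_true and A0 must be positive")
        if self.noise_sd < 0 or self.replicates < 1:
            raise ConfigError("noise_sd must be >= 0 and replicates >= 1")
        if any(c < 0 for c in self.concentrations):
            raise ConfigError("concentrations must be >= 0")


def simulate_growth(config: GrowthSimConfig) -> list[GrowthCurve]:
    """One GrowthCurve per concentration, shape (n_times, replicates)."""
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.times, dtype=float)
    curves = []
    for S in config.concentrations:
        rate = config.k_max * S / (config.k_G_true + S)
        k = LN2 * rate
        if config.plateau_od is None:
            clean = config.A0 * np.exp(k * t)
        else:
            K, A0 = config.plateau_od, config.A0
            e = np.exp(k * t)
            clean = K * A0 * e / (K + A0 * (e - 1.0))
        od = clean[:, None] * np.exp(
            rng.normal(0.0, config.noise_sd, size=(t.size, config.replicates))
        )
        curves.append(GrowthCurve(substrate_conc=S, times=t, od=od))
    return curves


def simulate_lane(
    abundances: Mapping[str, float],
    incidence: IncidenceMatrix,
    reference_intensity: float = 1000.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    lane_id: str = "sim",
    condition: str = "simulated",
) -> LaneDensitometry:
    """Forward-simulate one gel lane under the mass model.

    Band intensity = Σ_v incidence[band, v]·abundance[v], then
    multiplicative log-normal noise; the loading-control intensity is
    noised the same way.
    """
    if any(a < 0 for a in abundances.values()):
        raise ConfigError("abundances must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.array([abundances[v] for v in incidence.variant_ids], dtype=float)
    clean = incidence.matrix.to_numpy(dtype=float) @ x
    noisy = clean * np.exp(rng.normal(0.0, noise_sd, size=clean.shape))
    ref = reference_intensity * float(np.exp(rng.normal(0.0, noise_sd)))
    bands = [
        (float(length), float(intensity))
        for length, intensity in zip(incidence.band_lengths, noisy)
    ]
    return LaneDensitometry(
        lane_id=lane_id, condition=condition, bands=bands, reference_intensity=ref
    )
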