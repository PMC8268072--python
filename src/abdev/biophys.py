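"""Aggregation-propensity profiling and charge/pI calculation.

The aggregation score is an openly specified surrogate in the Zyggregator
family: a per-residue intrinsic score combining z-scored hydrophobicity
and secondary-structure propensities with a charge penalty,

    a_res(i) = w_h * z_H(aa_i) + w_b * z_B(aa_i)
             - w_a * z_A(aa_i) - w_q * |q(aa_i)|

smoothed over 7-mer windows (A_res), corrected for the folded state by
solvent-exposure weighting (S_res), and accumulated over spatial or
sequence neighborhoods for the surface track (T_res). Summary totals are
positive-part sums by default (aggregation is driven by hotspots, not
offset by protective regions); plain sums are available by flag.

Net charge and isoelectric point use Henderson-Hasselbalch sums over an
EMBOSS-style pKa table with one N- and C-terminus per chain. Computed pI
values are sequence-level estimates and are not expected to match
capillary isoelectric focusing on a glycosylated antibody; only ordering
and shifts are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence
import warnings

import numpy as np

from .errors import ConfigError, DataError
from .structure import ExposureProfile, StructureModel, _representative_atoms
from ._tables import (
    ACIDIC_GROUPS,
    AMINO_ACIDS,
    BASIC_GROUPS,
    CHARGE_AT_PH7,
    CHOU_FASMAN_ALPHA,
    CHOU_FASMAN_BETA,
    DEFAULT_PKA,
    KYTE_DOOLITTLE,
)


def _zscore(scale: Mapping[str, float]) -> dict[str, float]:
    values = np.array([scale[aa] for aa in AMINO_ACIDS])
    mu, sd = values.mean(), values.std()
    return {aa: (scale[aa] - mu) / sd for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class PropensityScales:
    """Residue scales and weights feeding the intrinsic score.

    Default weights put more mass on beta-sheet promotion than on helix
    protection (beta structure drives amyloid-like self-association;
    helicity only partially protects), which also keeps every canonical
    hydrophobic residue above Ser/Thr on the intrinsic scale — the
    ordering the hydrophobicity-reduction design rule relies on.
    """

    hydrophobicity: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    beta_propensity: Mapping[str, float] = field(default_factory=lambda: dict(CHOU_FASMAN_BETA))
    alpha_propensity: Mapping[str, float] = field(default_factory=lambda: dict(CHOU_FASMAN_ALPHA))
    charge: Mapping[str, float] = field(default_factory=lambda: dict(CHARGE_AT_PH7))
    w_h: float = 1.0
    w_b: float = 0.6
    w_a: float = 0.4
    w_q: float = 1.0

    def __post_init__(self) -> None:
        for name, scale in (
            ("hydrophobicity", self.hydrophobicity),
            ("beta_propensity", self.beta_propensity),
            ("alpha_propensity", self.alpha_propensity),
            ("charge", self.charge),
        ):
            missing = set(AMINO_ACIDS) - set(scale)
            if missing:
                raise ConfigError(f"scale {name} missing residues {sorted(missing)}")

    def intrinsic(self, aa: str) -> float:
        zh, zb, za = (
            _zscore(self.hydrophobicity),
            _zscore(self.beta_propensity),
            _zscore(self.alpha_propensity),
        )
        return (
            self.w_h * zh[aa]
            + self.w_b * zb[aa]
            - self.w_a * za[aa]
            - self.w_q * abs(self.charge[aa])
        )


@dataclass(frozen=True)
class AggregationProfile:
    sequence: str
    a_res: tuple[float, ...]
    A_res: tuple[float, ...]
    S_res: Optional[tuple[float, ...]]
    T_res: Optional[tuple[float, ...]]
    A_tot: float
    S_tot: Optional[float]
    T_tot: Optional[float]
    hotspots: tuple[tuple[int, int, str, float], ...]  # (start, end, track, peak)


def intrinsic_profile(seq: str, scales: PropensityScales = PropensityScales()) -> np.ndarray:
    """Per-residue intrinsic aggregation score in z-units."""
    zh = _zscore(scales.hydrophobicity)
    zb = _zscore(scales.beta_propensity)
    za = _zscore(scales.alpha_propensity)
    out = np.zeros(len(seq))
    for i, aa in enumerate(seq):
        if aa not in zh:
            warnings.warn(f"unknown residue {aa!r} at position {i + 1}; contributes 0")
            continue
        out[i] = (
            scales.w_h * zh[aa]
            + scales.w_b * zb[aa]
            - scales.w_a * za[aa]
            - scales.w_q * abs(scales.charge[aa])
        )
    return out


def _total(track: np.ndarray, positive_part: bool = True) -> float:
    return float(np.maximum(track, 0.0).sum() if positive_part else track.sum())


def window_profile(
    a_res: np.ndarray, window: int = 7, positive_part: bool = True
) -> tuple[np.ndarray, float]:
    """Sliding-window mean over overlapping ``window``-mers, plus A_tot.

    Windows are centered and truncated at the edges; a window longer than
    the sequence degenerates to a single full-sequence mean.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError("window must be odd and >= 1")
    n = len(a_res)
    if n == 0:
        raise DataError("empty track")
    if window > n:
        A = np.full(n, a_res.mean())
        return A, _total(A, positive_part)
    half = window // 2
    A = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        A[i] = a_res[lo:hi].mean()
    return A, _total(A, positive_part)


def conformational_profile(
    A_res: np.ndarray, exposure: ExposureProfile, positive_part: bool = True
) -> tuple[np.ndarray, float]:
    """Fold-corrected track: windowed propensity weighted by exposure."""
    rel = np.asarray(exposure.relative)
    if len(rel) != len(A_res):
        raise DataError("exposure profile length does not match track")
    S = A_res * rel
    return S, _total(S, positive_part)


def surface_profile(
    a_res: np.ndarray,
    exposure: ExposureProfile,
    model: Optional[StructureModel] = None,
    chain_id: Optional[str] = None,
    radius: float = 10.0,
    seq_window: int = 4,
    positive_part: bool = True,
) -> tuple[np.ndarray, float]:
    """Surface aggregation track: exposure-weighted propensity accumulated
    over a spatial patch (representative atoms within ``radius``) or, in
    sequence-only mode, over the window i +/- ``seq_window``."""
    if radius <= 0:
        raise ConfigError("patch radius must be positive")
    rel = np.asarray(exposure.relative)
    if len(rel) != len(a_res):
        raise DataError("exposure profile length does not match track")
    contrib = a_res * rel
    n = len(a_res)
    T = np.zeros(n)
    if model is not None:
        reps = [
            (model.sequence_position(cid, ridx), xyz)
            for cid, ridx, xyz in _representative_atoms(model)
            if chain_id is None or cid == chain_id
        ]
        pos = {p: xyz for p, xyz in reps}
        coords = {p: xyz for p, xyz in pos.items() if 1 <= p <= n}
        for i in range(n):
            xyz_i = coords.get(i + 1)
            if xyz_i is None:
                T[i] = contrib[i]
                continue
            for j, xyz_j in coords.items():
                if np.linalg.norm(xyz_i - xyz_j) <= radius:
                    T[i] += contrib[j - 1]
    else:
        for i in range(n):
            lo, hi = max(0, i - seq_window), min(n, i + seq_window + 1)
            T[i] = contrib[lo:hi].sum()
    return T, _total(T, positive_part)


def hotspots(
    track: np.ndarray, threshold_sd: float = 1.0, min_run: int = 3, track_name: str = "A_res"
) -> list[tuple[int, int, str, float]]:
    """Maximal runs of at least ``min_run`` positions at or above
    mean + threshold_sd * sd of the track. A constant track (sd 0) has no
    hotspots by definition. Intervals are 1-based inclusive."""
    track = np.asarray(track)
    if track.size == 0:
        raise DataError("empty track")
    sd = track.std()
    if sd == 0:
        return []
    cutoff = track.mean() + threshold_sd * sd
    above = track >= cutoff
    out = []
    i = 0
    n = len(track)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                peak = float(track[i : j + 1].max())
                out.append((i + 1, j + 1, track_name, peak))
            i = j + 1
        else:
            i += 1
    return out


def aggregation_profile(
    seq: str,
    exposure: Optional[ExposureProfile] = None,
    model: Optional[StructureModel] = None,
    chain_id: Optional[str] = None,
    scales: PropensityScales = PropensityScales(),
    window: int = 7,
    radius: float = 10.0,
    positive_part: bool = True,
) -> AggregationProfile:
    """Full per-chain profile: intrinsic, windowed, fold-corrected and
    surface tracks with totals and per-track hotspots."""
    a = intrinsic_profile(seq, scales)
    A, A_tot = window_profile(a, window, positive_part)
    S = S_tot = T = T_tot = None
    spots = list(hotspots(A, track_name="A_res"))
    if exposure is not None:
        S, S_tot = conformational_profile(A, exposure, positive_part)
        T, T_tot = surface_profile(
            a, exposure, model=model, chain_id=chain_id, radius=radius,
            positive_part=positive_part,
        )
        spots += hotspots(S, track_name="S_res") + hotspots(T, track_name="T_res")
    return AggregationProfile(
        sequence=seq,
        a_res=tuple(a),
        A_res=tuple(A),
        S_res=None if S is None else tuple(S),
        T_res=None if T is None else tuple(T),
        A_tot=A_tot,
        S_tot=S_tot,
        T_tot=T_tot,
        hotspots=tuple(spots),
    )


@dataclass(frozen=True)
class ChargeModel:
    """Ionisable groups and their pKa values (one N/C terminus per chain)."""

    pka: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    include_termini: bool = True

    def __post_init__(self) -> None:
        for group, value in self.pka.items():
            if not 0.0 < value < 14.0:
                raise ConfigError(f"pKa for {group} outside (0, 14): {value}")


def _group_counts(seq, model: ChargeModel) -> dict[str, int]:
    """Ionisable group counts; ``seq`` may be one chain or several
    (termini counted once per chain)."""
    chains = [seq] if isinstance(seq, str) else list(seq)
    counts = {g: 0 for g in model.pka}
    for chain in chains:
        for aa in chain:
            if aa in counts:
                counts[aa] += 1
        if model.include_termini:
            counts["Nterm"] = counts.get("Nterm", 0) + 1
            counts["Cterm"] = counts.get("Cterm", 0) + 1
    return counts


def net_charge(seq: str, pH, model: ChargeModel = ChargeModel()):
    """Henderson-Hasselbalch net charge at ``pH`` (scalar or array)."""
    pH = np.asarray(pH, dtype=float)
    if np.any((pH <= 0) | (pH >= 14)):
        raise ConfigError("pH must lie in (0, 14)")
    counts = _group_counts(seq, model)
    charge = np.zeros_like(pH)
    for group, count in counts.items():
        if count == 0:
            continue
        pka = model.pka[group]
        if group in BASIC_GROUPS:
            charge = charge + count / (1.0 + 10.0 ** (pH - pka))
        elif group in ACIDIC_GROUPS:
            charge = charge - count / (1.0 + 10.0 ** (pka - pH))
        else:
            raise ConfigError(f"pKa group {group!r} not classified as acidic or basic")
    return float(charge) if charge.ndim == 0 else charge


def isoelectric_point(
    seq: str, model: ChargeModel = ChargeModel(), tol: float = 1e-4
) -> float:
    """pH of zero net charge by bisection on (0, 14); deterministic."""
    counts = _group_counts(seq, model)
    if not any(counts.values()):
        raise DataError("sequence has no ionizable groups")
    lo, hi = 1e-6, 14.0 - 1e-6
    f_lo, f_hi = net_charge(seq, lo, model), net_charge(seq, hi, model)
    if f_lo < 0 or f_hi > 0:
        raise DataError("net charge does not change sign on (0, 14)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = net_charge(seq, mid, model)
        if abs(f_mid) < tol:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
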