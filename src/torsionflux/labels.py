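"""Fluctuation labels from ensemble dihedrals.

The per-residue flexibility target is the wrapped standard deviation of
each backbone dihedral across the models of an ensemble, divided by 180
so that labels are dimensionless in [0, 1].  The module also applies
the dataset-curation filters (minimum model count, minimum length, only
standard residues) and provides the distribution / dphi-dpsi
correlation summaries used to characterise a label set.

Circular statistics conventions: the mean direction comes from unit-
vector averaging; deviations from it are wrapped into (-180, 180]
before squaring.  The wrapped deviation is therefore bounded by 180
degrees, which is what makes the /180 normalization map onto [0, 1].
Dispersion uses the population (1/M) normalization by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DihedralSeries, EnsembleStructure

__all__ = [
    "FluctuationProfile",
    "FilterReport",
    "CircularDegeneracyError",
    "circular_mean",
    "circular_fluctuation",
    "normalize_fluctuation",
    "fluctuation_profile",
    "apply_dataset_filters",
    "fluctuation_histogram",
    "dphi_dpsi_correlation",
    "profiles_to_frame",
    "write_labels_tsv",
    "read_labels_tsv",
]


class CircularDegeneracyError(ValueError):
    """Mean direction undefined: resultant vector has (near-)zero length."""


@dataclass
class FluctuationProfile:
    """Normalized per-residue torsion-angle fluctuations for one chain."""

    chain_id: str
    dphi: np.ndarray
    dpsi: np.ndarray
    dphi_defined: np.ndarray
    dpsi_defined: np.ndarray
    sequence: str = ""

    def __post_init__(self) -> None:
        for arr in (self.dphi, self.dpsi):
            ok = np.asarray(arr)[~np.isnan(np.asarray(arr))]
            if ok.size and (ok.min() < 0 or ok.max() > 1):
                raise ValueError("normalized fluctuations must lie in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.dphi)


@dataclass
class FilterReport:
    """Accounting of dataset filtering, one removal reason per chain."""

    n_input: int
    removed_model_count: list[str] = field(default_factory=list)
    removed_length: list[str] = field(default_factory=list)
    removed_nonstandard: list[str] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_model_count": self.removed_model_count,
            "removed_length": self.removed_length,
            "removed_nonstandard": self.removed_nonstandard,
            "survivors": self.survivors,
        }


def _wrap_degrees(a):
    """Wrap angles into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped


def circular_mean(angles) -> float:
    """Mean direction of angles in degrees, in (-180, 180].

    Undefined (raises) when the resultant length is numerically zero,
    e.g. for an antipodal pair like {0, 180}.
    """
    a = np.radians(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("circular_mean of an empty set")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    if np.hypot(s, c) <= 1e-12:
        raise CircularDegeneracyError("resultant length ~ 0; mean direction undefined")
    return float(_wrap_degrees(np.degrees(np.arctan2(s, c))))


def circular_fluctuation(angles, ddof: int = 0) -> float:
    """Wrapped standard deviation about the circular mean, degrees in [0, 180].

    sigma = sqrt( (1/M) * sum( wrap(theta_m - mean)^2 ) ) with deviations
    wrapped into (-180, 180].  ``ddof=1`` switches to the sample (1/(M-1))
    normalization.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 angles to measure fluctuation")
    mu = circular_mean(a)
    dev = _wrap_degrees(a - mu)
    return float(np.sqrt(np.sum(dev**2) / (a.size - ddof)))


def normalize_fluctuation(sigma: float) -> float:
    """Map a wrapped deviation in degrees onto the dimensionless [0, 1] scale."""
    sigma = float(sigma)
    if not 0.0 <= sigma <= 180.0:
        raise ValueError(f"sigma out of range [0, 180]: {sigma}")
    return sigma / 180.0


def _per_residue_sigma(angles: np.ndarray, defined: np.ndarray, ddof: int) -> np.ndarray:
    M, L = angles.shape
    out = np.full(L, np.nan)
    for i in range(L):
        vals = angles[defined[:, i], i]
        if vals.size < 2:
            continue
        try:
            out[i] = normalize_fluctuation(circular_fluctuation(vals, ddof=ddof))
        except CircularDegeneracyError:
            continue  # stays undefined
    return out


def fluctuation_profile(d: DihedralSeries, ddof: int = 0, sequence: str = "") -> FluctuationProfile:
    """Per-residue normalized dphi/dpsi labels from a dihedral series.

    A position is undefined when fewer than two models define the angle
    there (termini always are) or when the circular mean degenerates.
    """
    if d.n_models < 2:
        raise ValueError("fluctuation labels need at least 2 models")
    dphi = _per_residue_sigma(d.phi, d.phi_defined, ddof)
    dpsi = _per_residue_sigma(d.psi, d.psi_defined, ddof)
    return FluctuationProfile(
        chain_id=d.chain_id,
        dphi=dphi,
        dpsi=dpsi,
        dphi_defined=~np.isnan(dphi),
        dpsi_defined=~np.isnan(dpsi),
        sequence=sequence,
    )


def apply_dataset_filters(
    chains: list[EnsembleStructure], min_models: int = 5, min_length: int = 25
) -> FilterReport:
    """Keep chains with >= min_models models, >= min_length residues and
    only standard residues.  Each removed chain is attributed to the
    first failing rule, rules checked in that order."""
    report = FilterReport(n_input=len(chains))
    for ch in chains:
        if ch.n_models < min_models:
            report.removed_model_count.append(ch.chain_id)
        elif ch.length < min_length:
            report.removed_length.append(ch.chain_id)
        elif ch.nonstandard:
            report.removed_nonstandard.append(ch.chain_id)
        else:
            report.survivors.append(ch.chain_id)
    return report


def _defined_values(profiles, attr):
    vals = [getattr(p, attr)[getattr(p, f"{attr}_defined")] for p in profiles]
    return np.concatenate(vals) if vals else np.array([])


def fluctuation_histogram(profiles, n_bins: int = 10):
    """Counts of defined labels in equal-width bins on [0, 1].

    Returns (counts_dphi, counts_dpsi, bin_edges); the last bin is
    right-closed so totals are conserved.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    dphi = _defined_values(profiles, "dphi")
    dpsi = _defined_values(profiles, "dpsi")
    if dphi.size + dpsi.size == 0:
        raise ValueError("no defined labels to histogram")
    return np.histogram(dphi, edges)[0], np.histogram(dpsi, edges)[0], edges


def dphi_dpsi_correlation(profiles) -> float:
    """Pearson correlation between dphi and dpsi over residues where both
    labels are defined."""
    xs, ys = [], []
    for p in profiles:
        both = p.dphi_defined & p.dpsi_defined
        xs.append(p.dphi[both])
        ys.append(p.dpsi[both])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    if x.size < 2:
        raise ValueError("need at least 2 residues with both labels defined")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Long-format label table: chain_id, residue_index, aa, dphi, dpsi, flags."""
    rows = []
    for p in profiles:
        seq = p.sequence or "X" * p.length
        for i in range(p.length):
            rows.append(
                {
                    "chain_id": p.chain_id,
                    "residue_index": i,
                    "aa": seq[i],
                    "dphi": p.dphi[i],
                    "dpsi": p.dpsi[i],
                    "dphi_defined": bool(p.dphi_defined[i]),
                    "dpsi_defined": bool(p.dpsi_defined[i]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chain_id",
            "residue_index",
            "aa",
            "dphi",
            "dpsi",
            "dphi_defined",
            "dpsi_defined",
        ],
    )


def write_labels_tsv(profiles, path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
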