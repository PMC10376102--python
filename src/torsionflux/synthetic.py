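"""Synthetic fixtures for every pipeline stage.

Two generators stand in for real data so that all stages are testable
end to end:

* :func:`synth_ensemble` plants per-residue angular noise: model m's
  phi_i/psi_i are wrapped-normal draws around per-residue base angles,
  realised as 3-D coordinates through the natural-extension builder.
  Measuring the ensemble therefore recovers the planted sigma/180
  profile (up to sampling error shrinking as 1/sqrt(M)).

* :func:`synth_features` plants a known linear signal: features are
  U(0, 1), labels combine chosen (offset, column) terms plus Gaussian
  noise, clipped to [0, 1].  The spec records the ground-truth
  informative set, enabling selection-recovery and window-sweep tests.

File writers emit the same PDB/FASTA/PSSM/TSV formats the real
pipeline reads, so fixtures double as format-conformance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import AA_ALPHABET, PSIBLAST_ORDER
from .geometry import EnsembleStructure, build_backbone, write_multimodel_pdb

__all__ = [
    "EnsembleSpec",
    "SignalSpec",
    "synth_ensemble",
    "synth_features",
    "write_ensemble_directory",
    "write_feature_directory",
    "random_sequence",
]


@dataclass
class EnsembleSpec:
    """Recipe for a planted-noise ensemble.

    sigma_phi / sigma_psi are angular noise SDs in degrees, scalar or
    per-residue arrays; base angles default to a helix-like backbone.
    """

    L: int = 30
    M: int = 10
    sigma_phi: float | np.ndarray = 10.0
    sigma_psi: float | np.ndarray = 10.0
    base_phi: float | np.ndarray = -57.0
    base_psi: float | np.ndarray = -47.0
    seed: int = 0
    chain_id: str = "synth_A"

    def __post_init__(self) -> None:
        if self.M < 1 or self.L < 1:
            raise ValueError("need M >= 1 models and L >= 1 residues")
        for s in (np.atleast_1d(self.sigma_phi), np.atleast_1d(self.sigma_psi)):
            if (np.asarray(s, float) < 0).any():
                raise ValueError("noise SD must be nonnegative")


@dataclass
class SignalSpec:
    """Recipe for planted-signal feature/label sets.

    ``terms`` is a list of (offset, column, coefficient): the label at
    residue i collects coefficient * (X[i + offset, column] - 0.5) for
    each term (out-of-range offsets contribute nothing, mirroring the
    zero-padding convention of windowing), plus N(0, noise_sd), around
    a 0.5 intercept, clipped to [0, 1].
    """

    n_chains: int = 20
    length: int = 25
    n_columns: int = 50
    terms: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, c, 0.35) for c in range(5)]
    )
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(not 0 <= c < self.n_columns for _, c, _ in self.terms):
            raise ValueError("informative columns must lie inside the feature space")

    @property
    def informative_columns(self) -> set[int]:
        return {c for _, c, _ in self.terms}


def random_sequence(L: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=L))


def _wrap(a):
    return -(np.mod(-np.asarray(a, float) + 180.0, 360.0) - 180.0)


def synth_ensemble(spec: EnsembleSpec) -> EnsembleStructure:
    """Realise a planted-noise ensemble as backbone coordinates."""
    rng = np.random.default_rng(spec.seed)
    base_phi = np.broadcast_to(np.asarray(spec.base_phi, float), (spec.L,))
    base_psi = np.broadcast_to(np.asarray(spec.base_psi, float), (spec.L,))
    s_phi = np.broadcast_to(np.asarray(spec.sigma_phi, float), (spec.L,))
    s_psi = np.broadcast_to(np.asarray(spec.sigma_psi, float), (spec.L,))
    sequence = random_sequence(spec.L, rng)
    coords = np.empty((spec.M, spec.L, 3, 3))
    for m in range(spec.M):
        phi = _wrap(base_phi + rng.normal(0.0, s_phi))
        psi = _wrap(base_psi + rng.normal(0.0, s_psi))
        coords[m] = build_backbone(phi, psi)
    return EnsembleStructure(chain_id=spec.chain_id, sequence=sequence, coords=coords)


def synth_features(spec: SignalSpec):
    """Generate per-chain feature matrices and labels with planted signal.

    Returns (features, labels): dicts keyed by chain id holding (L, D)
    U(0,1) feature arrays and (L,) labels in [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    features: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for c in range(spec.n_chains):
        cid = f"chain{c:03d}"
        X = rng.random((spec.length, spec.n_columns))
        y = np.full(spec.length, 0.5)
        for off, col, coeff in spec.terms:
            lo = max(0, -off)
            hi = min(spec.length, spec.length - off)
            idx = np.arange(lo, hi)
            y[idx] += coeff * (X[idx + off, col] - 0.5)
        y += rng.normal(0.0, spec.noise_sd, size=spec.length)
        features[cid] = X
        labels[cid] = np.clip(y, 0.0, 1.0)
    return features, labels


def write_ensemble_directory(out_dir, specs) -> list[Path]:
    """Write one multi-model PDB per ensemble spec; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for spec in specs:
        e = synth_ensemble(spec)
        p = out_dir / f"{spec.chain_id}.pdb"
        write_multimodel_pdb(e, p)
        paths.append(p)
    return paths


def _write_pssm_ascii(path, sequence: str, scores: np.ndarray) -> None:
    """Write integer log-odds scores in PSI-BLAST ASCII layout."""
    lines = ["", "Last position-specific scoring matrix computed", "   " + "  ".join(PSIBLAST_ORDER)]
    for i, aa in enumerate(sequence):
        row = " ".join(f"{int(v):3d}" for v in scores[i])
        lines.append(f"{i + 1:5d} {aa} {row}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_feature_directory(out_dir, chain_ids, length: int = 30, seed: int = 0) -> None:
    """Emit per-chain FASTA, PSSM (PSI-BLAST ASCII) and TSV feature files.

    For each chain id the directory gains ``{id}.fasta``, ``{id}.pssm``,
    ``{id}.struct.tsv`` (asa, ss_H, ss_C, ss_E, ssb_H, ssb_C, ssb_E) and
    ``{id}.flex.tsv`` (disorder, dphi_pred, dpsi_pred, psee).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    for cid in chain_ids:
        seq = random_sequence(length, rng)
        (out_dir / f"{cid}.fasta").write_text(f">{cid}\n{seq}\n")
        scores = rng.integers(-6, 9, size=(length, 20))
        # scores are written in PSI-BLAST column order
        _write_pssm_ascii(out_dir / f"{cid}.pssm", seq, scores)
        ss = rng.dirichlet(np.ones(3), size=length)
        ssb = rng.dirichlet(np.ones(3), size=length)
        struct = pd.DataFrame(
            np.column_stack([rng.random(length), ss, ssb]),
            columns=["asa", "ss_H", "ss_C", "ss_E", "ssb_H", "ssb_C", "ssb_E"],
        )
        struct.to_csv(out_dir / f"{cid}.struct.tsv", sep="\t", index=False)
        flex = pd.DataFrame(
            {
                "disorder": rng.random(length),
                "dphi_pred": rng.random(length),
                "dpsi_pred": rng.random(length),
                "psee": rng.normal(0.0, 1.0, size=length),
            }
        )
        flex.to_csv(out_dir / f"{cid}.flex.tsv", sep="\t", index=False)
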