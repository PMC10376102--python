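"""Per-residue feature assembly and sliding-window concatenation.

Five feature groups are assembled into an L x D matrix per chain:

* residue      (20)  one-hot amino-acid identity
* physiochemical (5) five-factor numeric pattern per amino acid
  (polarity, secondary-structure propensity, molecular volume, codon
  diversity, electrostatic charge)
* pssm         (20)  logistic-normalized position-specific scoring matrix
* monogram      (1)  per-residue mean of the normalized PSSM row
* bigram       (20)  expected forward-transition products of consecutive
                     normalized PSSM rows
* structural    (7)  predicted ASA plus two sets of H/C/E secondary-
                     structure probabilities
* flexibility   (4)  disorder probability, predicted dphi/dpsi, PSEE

The documented default layout totals D = 77 columns.  A sliding window
of odd width ws concatenates each residue's row with its neighbours
(zero-padded or edge-replicated at the termini) into L x (D * ws).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "PSIBLAST_ORDER",
    "FeatureMatrix",
    "WindowedMatrix",
    "GROUP_WIDTHS",
    "load_factor_table",
    "residue_profile",
    "physiochemical_profile",
    "load_pssm",
    "normalize_pssm",
    "monogram",
    "bigram",
    "structural_profile",
    "flexibility_profile",
    "assemble",
    "default_feature_matrix",
    "window",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# column order of the first 20 score columns in PSI-BLAST ASCII output
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWVY"

GROUP_WIDTHS = {
    "residue": 20,
    "physiochemical": 5,
    "pssm": 20,
    "monogram": 1,
    "bigram": 20,
    "structural": 7,
    "flexibility": 4,
}


@dataclass
class FeatureMatrix:
    """L x D per-residue features with (group, column) metadata."""

    chain_id: str
    values: np.ndarray
    columns: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (L x D)")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column metadata length must equal feature width")
        if np.isnan(self.values).any():
            raise ValueError("assembled features must not contain NaN")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowedMatrix:
    """Window-concatenated features: row i holds offsets -h..+h of the source."""

    chain_id: str
    values: np.ndarray
    ws: int
    columns: list[tuple[int, str, str]]  # (offset, group, column)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def load_factor_table() -> pd.DataFrame:
    """The shipped 20 x 5 amino-acid factor table, indexed by one-letter code."""
    ref = importlib.resources.files("torsionflux.data") / "atchley_factors.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", index_col="aa")


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"nonstandard residue letter(s) {sorted(bad)} in sequence")


def residue_profile(sequence: str) -> np.ndarray:
    """One-hot encoding over the 20 standard amino acids (alphabetical order)."""
    _check_sequence(sequence)
    idx = np.array([AA_ALPHABET.index(a) for a in sequence])
    out = np.zeros((len(sequence), 20))
    out[np.arange(len(sequence)), idx] = 1.0
    return out


def physiochemical_profile(sequence: str, factor_table: pd.DataFrame | None = None) -> np.ndarray:
    """Row lookup of the five-factor numeric pattern for each residue."""
    table = load_factor_table() if factor_table is None else factor_table
    missing = set(sequence) - set(table.index)
    if missing:
        raise ValueError(f"factor table lacks residue(s) {sorted(missing)}")
    return table.loc[list(sequence)].to_numpy(dtype=float)


def normalize_pssm(scores: np.ndarray) -> np.ndarray:
    """Logistic transform 1 / (1 + exp(-x)) of raw log-odds scores."""
    return 1.0 / (1.0 + np.exp(-np.asarray(scores, dtype=float)))


def _parse_psiblast_ascii(text: str) -> np.ndarray:
    rows = []
    for line in text.splitlines():
        parts = line.split()
        # data rows: index, residue letter, then >= 20 integer scores
        if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
            rows.append([int(v) for v in parts[2:22]])
    if not rows:
        raise ValueError("no PSSM data rows found (PSI-BLAST ASCII layout expected)")
    return np.asarray(rows, dtype=float)


def load_pssm(path, sequence: str | None = None) -> np.ndarray:
    """Read a PSSM (PSI-BLAST ASCII, or TSV fallback) and normalize it.

    Raw integer log-odds scores are mapped through the logistic function
    into (0, 1).  Columns are reordered from PSI-BLAST's layout to the
    package's alphabetical amino-acid order.  With ``sequence`` given,
    a row-count mismatch raises.
    """
    text = open(path).read()
    try:
        scores = _parse_psiblast_ascii(text)
        order = [PSIBLAST_ORDER.index(a) for a in AA_ALPHABET]
        scores = scores[:, order]
    except ValueError:
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c in set(AA_ALPHABET)]
        if len(cols) != 20:
            raise ValueError(f"{path}: neither PSI-BLAST ASCII nor 20-column TSV")
        scores = df[list(AA_ALPHABET)].to_numpy(dtype=float)
    if sequence is not None and scores.shape[0] != len(sequence):
        raise ValueError(
            f"{path}: {scores.shape[0]} PSSM rows for {len(sequence)} residues"
        )
    return normalize_pssm(scores)


def monogram(pssm_block: np.ndarray) -> np.ndarray:
    """MG(i) = mean over the 20 profile values of row i; shape L x 1."""
    p = np.asarray(pssm_block, dtype=float)
    if p.ndim != 2 or p.shape[1] != 20:
        raise ValueError("expected an L x 20 normalized PSSM block")
    return p.mean(axis=1, keepdims=True)


def bigram(pssm_block: np.ndarray) -> np.ndarray:
    """BG_k(i) = (1/20) * sum_j P(i, j) * P(i+1, k); shape L x 20.

    The last residue has no successor; its row uses the self-transition
    fallback P(i+1) = P(i).
    """
    p = np.asarray(pssm_block, dtype=float)
    if p.ndim != 2 or p.shape[1] != 20 or p.shape[0] < 1:
        raise ValueError("expected a non-empty L x 20 normalized PSSM block")
    nxt = np.vstack([p[1:], p[-1:]])
    return p.mean(axis=1, keepdims=True) * nxt


def _clip_unit(arr: np.ndarray, name: str) -> np.ndarray:
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        warnings.warn(f"{name} values outside [0, 1]; clipping", stacklevel=3)
        arr = np.clip(arr, 0.0, 1.0)
    return arr


def _column(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(-1)
    return a


def structural_profile(asa, ss_probs, balanced_ss_probs) -> np.ndarray:
    """Seven structural columns: [ASA, H, C, E, H_bal, C_bal, E_bal]."""
    asa = _column(asa, "asa")
    ss = np.asarray(ss_probs, dtype=float)
    ssb = np.asarray(balanced_ss_probs, dtype=float)
    if ss.shape != (asa.size, 3) or ssb.shape != (asa.size, 3):
        raise ValueError("ASA and both SS blocks must share length; SS blocks are L x 3")
    ss = _clip_unit(ss, "secondary-structure probabilities")
    ssb = _clip_unit(ssb, "balanced secondary-structure probabilities")
    return np.column_stack([asa, ss, ssb])


def flexibility_profile(disorder, pred_dphi, pred_dpsi, psee=None) -> np.ndarray:
    """Four flexibility columns: [disorder, dphi_pred, dpsi_pred, psee].

    A missing PSEE track (None) is imputed with the per-chain mean of
    the other flexibility columns' scale -- in practice the disorder
    mean, keeping the column present and NaN-free.
    """
    disorder = _clip_unit(_column(disorder, "disorder"), "disorder probability")
    dphi_p = _column(pred_dphi, "pred_dphi")
    dpsi_p = _column(pred_dpsi, "pred_dpsi")
    L = disorder.size
    if psee is None:
        psee_col = np.full(L, float(disorder.mean()) if L else 0.0)
    else:
        psee_col = _column(psee, "psee")
        if np.isnan(psee_col).any():
            fill = float(np.nanmean(psee_col)) if not np.isnan(psee_col).all() else 0.0
            psee_col = np.where(np.isnan(psee_col), fill, psee_col)
    if not (dphi_p.size == dpsi_p.size == psee_col.size == L):
        raise ValueError("flexibility tracks must share length")
    return np.column_stack([disorder, dphi_p, dpsi_p, psee_col])


_GROUP_COLUMN_NAMES = {
    "residue": list(AA_ALPHABET),
    "physiochemical": [
        "polarity",
        "secondary_structure",
        "molecular_volume",
        "codon_diversity",
        "electrostatic_charge",
    ],
    "pssm": list(AA_ALPHABET),
    "monogram": ["mg"],
    "bigram": [f"bg_{a}" for a in AA_ALPHABET],
    "structural": ["asa", "ss_H", "ss_C", "ss_E", "ssb_H", "ssb_C", "ssb_E"],
    "flexibility": ["disorder", "dphi_pred", "dpsi_pred", "psee"],
}


def assemble(blocks: list[tuple[str, np.ndarray]], chain_id: str = "") -> FeatureMatrix:
    """Horizontally concatenate named feature blocks into a FeatureMatrix.

    Blocks are joined in the given order; metadata records each column's
    (group, name).  All blocks must share L.  The default seven-group
    layout totals 77 columns.
    """
    if not blocks:
        raise ValueError("no feature blocks to assemble")
    lengths = {b.shape[0] for _, b in blocks}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent block lengths: {sorted(lengths)}")
    columns: list[tuple[str, str]] = []
    for name, block in blocks:
        names = _GROUP_COLUMN_NAMES.get(name)
        if names is not None and block.shape[1] != len(names):
            raise ValueError(
                f"group '{name}' has width {block.shape[1]}, expected {len(names)}"
            )
        if names is None:
            names = [f"{name}_{j}" for j in range(block.shape[1])]
        columns.extend((name, n) for n in names)
    values = np.hstack([np.asarray(b, dtype=float) for _, b in blocks])
    return FeatureMatrix(chain_id=chain_id, values=values, columns=columns)


def default_feature_matrix(
    sequence: str,
    pssm: np.ndarray,
    asa,
    ss_probs,
    balanced_ss_probs,
    disorder,
    pred_dphi,
    pred_dpsi,
    psee=None,
    chain_id: str = "",
    groups: list[str] | None = None,
    factor_table: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Assemble the documented default layout (77 columns) for one chain."""
    available = {
        "residue": lambda: residue_profile(sequence),
        "physiochemical": lambda: physiochemical_profile(sequence, factor_table),
        "pssm": lambda: np.asarray(pssm, dtype=float),
        "monogram": lambda: monogram(pssm),
        "bigram": lambda: bigram(pssm),
        "structural": lambda: structural_profile(asa, ss_probs, balanced_ss_probs),
        "flexibility": lambda: flexibility_profile(disorder, pred_dphi, pred_dpsi, psee),
    }
    order = groups or list(GROUP_WIDTHS)
    unknown = set(order) - set(available)
    if unknown:
        raise ValueError(f"unknown feature group(s): {sorted(unknown)}")
    return assemble([(g, available[g]()) for g in order], chain_id=chain_id)


def window(m: FeatureMatrix | np.ndarray, ws: int, pad: str = "zero") -> WindowedMatrix:
    """Sliding-window concatenation of per-residue rows.

    Row i of the result concatenates source rows i-h .. i+h for
    h = (ws - 1) / 2.  Out-of-range offsets are zero-filled (``pad="zero"``)
    or replicate the terminal row (``pad="edge"``).
    """
    if ws < 1 or ws % 2 == 0:
        raise ValueError("window size must be odd and >= 1")
    if pad not in ("zero", "edge"):
        raise ValueError("pad must be 'zero' or 'edge'")
    if isinstance(m, FeatureMatrix):
        values, cols, cid = m.values, m.columns, m.chain_id
    else:
        values = np.asarray(m, dtype=float)
        cols = [("feature", f"f{j}") for j in range(values.shape[1])]
        cid = ""
    L, D = values.shape
    h = (ws - 1) // 2
    if pad == "zero":
        padded = np.vstack([np.zeros((h, D)), values, np.zeros((h, D))])
    else:
        padded = np.vstack([np.repeat(values[:1], h, 0), values, np.repeat(values[-1:], h, 0)])
    out = np.hstack([padded[k : k + L] for k in range(ws)])
    columns = [(off, g, n) for off in range(-h, h + 1) for g, n in cols]
    return WindowedMatrix(chain_id=cid, values=out, ws=ws, columns=columns)
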