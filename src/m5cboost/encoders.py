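"""Seven sequence feature encodings for fixed-length RNA windows.

For a 41-nt window the families and their dimensions are

====================  ====  ==========================================
ENAC                   148  sliding-window nucleotide composition
CKSNAP                  96  k-spaced nucleotide pair frequencies, k=0..5
ANF                     41  accumulated nucleotide frequency (density)
NCP                    123  3-bit nucleotide chemical property code
BIN                    164  per-position one-hot encoding
SCPDNC                 136  series-correlation pseudo dinucleotide comp.
W2V                    100  mean of learned k-mer word vectors
====================  ====  ==========================================

for 808 features in total, always in this block order with stable column
names, so that feature rankings and trained-model column contracts can be
exchanged as plain text.

All encoders operate on integer-coded sequence matrices internally (A=0,
C=1, G=2, U=3) and are vectorized across segments.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from m5cboost._util import ALPHABET, encode_nt
from m5cboost.sequence_io import SegmentSet
from m5cboost.word2vec import Word2VecModel, tokenize, train_cbow

BLOCK_ORDER = ("ENAC", "CKSNAP", "ANF", "NCP", "BIN", "SCPDNC", "W2V")

#: printed 3-bit chemical-property code: ring structure / functional group /
#: hydrogen bond classes collapsed to one triple per nucleotide.
NCP_CODE = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (0, 0, 1),
    "U": (1, 0, 0),
}

DINUCLEOTIDES = [a + b for a in ALPHABET for b in ALPHABET]


@dataclasses.dataclass
class EncoderConfig:
    """Tunable encoder parameters.

    enac_window
        sliding window size S for ENAC (default 5).
    cksnap_max_gap
        largest gap k between paired nucleotides (default 5; k runs 0..5).
    pse_lambda, pse_weight
        highest correlation tier and weight w for SCPseDNC (defaults 20, 0.9).
    embed_dim, embed_window, embed_epochs, embed_negative, token_k
        CBOW word-embedding hyperparameters; tokens are overlapping
        ``token_k``-mers with stride 1.
    blocks
        which feature families to emit, in canonical order.
    """

    enac_window: int = 5
    cksnap_max_gap: int = 5
    pse_lambda: int = 20
    pse_weight: float = 0.9
    embed_dim: int = 100
    embed_window: int = 5
    embed_epochs: int = 20
    embed_negative: int = 5
    token_k: int = 3
    blocks: tuple[str, ...] = BLOCK_ORDER

    def __post_init__(self) -> None:
        if not 0 < self.pse_weight <= 1:
            raise ValueError("pse_weight must be in (0, 1]")
        unknown = set(self.blocks) - set(BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
        self.blocks = tuple(b for b in BLOCK_ORDER if b in self.blocks)


class DinucleotidePropertyTable:
    """Physicochemical index values for the 16 RNA dinucleotides.

    Rows are z-standardized across the 16 dinucleotides at construction, as
    the pseudo-composition correlation formula presumes (each index then has
    mean 0 and unit variance, so different physical units are comparable).
    """

    def __init__(self, values: pd.DataFrame, standardize: bool = True):
        missing = set(DINUCLEOTIDES) - set(values.columns)
        if missing:
            raise ValueError(f"property table missing dinucleotides: {sorted(missing)}")
        values = values.loc[:, DINUCLEOTIDES].astype(float)
        if standardize:
            arr = values.to_numpy()
            arr = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(
                axis=1, keepdims=True
            )
            values = pd.DataFrame(arr, index=values.index, columns=values.columns)
        self.values = values

    @property
    def index_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_indices(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        """(n_indices, 16) array in lexicographic dinucleotide order."""
        return self.values.to_numpy()

    @classmethod
    def default(cls) -> "DinucleotidePropertyTable":
        """The bundled six RNA helical step indices (Roll, Rise, Shift,
        Twist, Slide, Tilt), z-standardized."""
        with resources.files("m5cboost.data").joinpath(
            "rna_dinucleotide_properties.tsv"
        ).open() as fh:
            table = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(table)


# ---------------------------------------------------------------------------
# vectorized encoders on integer code matrices
# ---------------------------------------------------------------------------


def _codes(sequences: Sequence[str]) -> np.ndarray:
    return np.stack([encode_nt(s) for s in sequences])


def _one_hot(codes: np.ndarray) -> np.ndarray:
    """(n, L, 4) one-hot in A,C,G,U order."""
    return np.eye(4)[codes]


def enac_matrix(codes: np.ndarray, window: int) -> np.ndarray:
    n, length = codes.shape
    if not 1 <= window <= length:
        raise ValueError(f"ENAC window {window} outside [1, {length}]")
    oh = _one_hot(codes)
    csum = np.concatenate(
        [np.zeros((n, 1, 4)), np.cumsum(oh, axis=1)], axis=1
    )
    counts = csum[:, window:, :] - csum[:, :-window, :]  # (n, L-S+1, 4)
    return (counts / window).reshape(n, -1)


def cksnap_matrix(codes: np.ndarray, max_gap: int) -> np.ndarray:
    n, length = codes.shape
    if max_gap > length - 2:
        raise ValueError("cksnap_max_gap exceeds sequence length - 2")
    blocks = []
    for k in range(max_gap + 1):
        first = codes[:, : length - k - 1]
        second = codes[:, k + 1 :]
        pair = first * 4 + second
        counts = np.zeros((n, 16))
        for p in range(16):
            counts[:, p] = (pair == p).sum(axis=1)
        blocks.append(counts / (length - k - 1))
    return np.concatenate(blocks, axis=1)


def anf_matrix(codes: np.ndarray) -> np.ndarray:
    n, length = codes.shape
    oh = _one_hot(codes)
    csum = np.cumsum(oh, axis=1)  # prefix counts per nucleotide
    own = np.take_along_axis(csum, codes[:, :, None], axis=2)[:, :, 0]
    return own / np.arange(1, length + 1)


def ncp_matrix(codes: np.ndarray) -> np.ndarray:
    lut = np.array([NCP_CODE[nt] for nt in ALPHABET], dtype=float)
    return lut[codes].reshape(codes.shape[0], -1)


def binary_matrix(codes: np.ndarray) -> np.ndarray:
    return _one_hot(codes).reshape(codes.shape[0], -1)


def scpsednc_matrix(
    codes: np.ndarray,
    lam: int,
    weight: float,
    table: DinucleotidePropertyTable,
) -> np.ndarray:
    """Series-correlation pseudo dinucleotide composition.

    16 normalized dinucleotide frequencies followed by lam * n_indices
    correlation factors theta, ordered tier-major (all indices of tier m=1,
    then m=2, ...).  Tier-m factors average the index-value product of
    dinucleotides m steps apart over i = 1..L-m-2.  The shared denominator
    1 + w * sum(theta) makes the full vector sum to exactly 1.
    """
    n, length = codes.shape
    if lam >= length - 2:
        raise ValueError(f"pse_lambda {lam} must be < L-2 = {length - 2}")
    prop = table.as_array()  # (Lam_idx, 16)
    n_idx = prop.shape[0]
    dinuc = codes[:, :-1] * 4 + codes[:, 1:]  # (n, L-1)
    freq = np.zeros((n, 16))
    for p in range(16):
        freq[:, p] = (dinuc == p).sum(axis=1)
    freq /= length - 1

    vals = prop[:, dinuc]  # (n_idx, n, L-1)
    thetas = np.empty((n, lam, n_idx))
    for m in range(1, lam + 1):
        upper = length - m - 2  # i runs 1..L-m-2 (1-based)
        prod = vals[:, :, :upper] * vals[:, :, m : m + upper]
        thetas[:, m - 1, :] = prod.mean(axis=2).T
    theta_flat = thetas.reshape(n, lam * n_idx)
    denom = 1.0 + weight * theta_flat.sum(axis=1, keepdims=True)
    return np.concatenate([freq, weight * theta_flat], axis=1) / denom


def word2vec_matrix(
    sequences: Sequence[str], model: Word2VecModel
) -> np.ndarray:
    out = np.zeros((len(sequences), model.dim))
    for i, seq in enumerate(sequences):
        out[i] = model.encode(seq)
    return out


# ---------------------------------------------------------------------------
# per-segment wrappers
# ---------------------------------------------------------------------------


def encode_enac(sequence: str, window: int = 5) -> np.ndarray:
    """Per-window nucleotide composition along a sliding window."""
    return enac_matrix(_codes([sequence]), window)[0]


def encode_cksnap(sequence: str, max_gap: int = 5) -> np.ndarray:
    """Frequencies of nucleotide pairs k positions apart, k = 0..max_gap."""
    return cksnap_matrix(_codes([sequence]), max_gap)[0]


def encode_anf(sequence: str) -> np.ndarray:
    """Accumulated frequency of each position's nucleotide over its prefix."""
    return anf_matrix(_codes([sequence]))[0]


def encode_ncp(sequence: str) -> np.ndarray:
    """Position-major 3-bit chemical-property code."""
    return ncp_matrix(_codes([sequence]))[0]


def encode_binary(sequence: str) -> np.ndarray:
    """Position-major one-hot code in A,C,G,U order."""
    return binary_matrix(_codes([sequence]))[0]


def encode_scpsednc(
    sequence: str,
    lam: int = 20,
    weight: float = 0.9,
    table: DinucleotidePropertyTable | None = None,
) -> np.ndarray:
    table = table or DinucleotidePropertyTable.default()
    return scpsednc_matrix(_codes([sequence]), lam, weight, table)[0]


def encode_word2vec(sequence: str, model: Word2VecModel) -> np.ndarray:
    """Mean of the segment's k-mer token vectors (OOV tokens count as zero)."""
    return model.encode(sequence)


def train_embedding(
    corpus: SegmentSet | Iterable[str], cfg: EncoderConfig, seed: int
) -> Word2VecModel:
    """Train the CBOW k-mer embedding on a segment corpus.

    Train only on the training split when a held-out evaluation follows —
    the embedding is part of the fitted pipeline.
    """
    sequences = [s.sequence for s in corpus] if isinstance(corpus, SegmentSet) else list(corpus)
    sentences = [tokenize(s, cfg.token_k) for s in sequences]
    return train_cbow(
        sentences,
        dim=cfg.embed_dim,
        window=cfg.embed_window,
        epochs=cfg.embed_epochs,
        negative=cfg.embed_negative,
        seed=seed,
        token_k=cfg.token_k,
    )


# ---------------------------------------------------------------------------
# feature matrix assembly
# ---------------------------------------------------------------------------


def feature_names(
    cfg: EncoderConfig, length: int = 41, table: DinucleotidePropertyTable | None = None
) -> dict[str, list[str]]:
    """Canonical column names per requested block."""
    table = table or DinucleotidePropertyTable.default()
    names: dict[str, list[str]] = {}
    if "ENAC" in cfg.blocks:
        names["ENAC"] = [
            f"ENAC_win{j}_{nt}"
            for j in range(1, length - cfg.enac_window + 2)
            for nt in ALPHABET
        ]
    if "CKSNAP" in cfg.blocks:
        names["CKSNAP"] = [
            f"CKSNAP_k{k}_{pair}"
            for k in range(cfg.cksnap_max_gap + 1)
            for pair in DINUCLEOTIDES
        ]
    if "ANF" in cfg.blocks:
        names["ANF"] = [f"ANF_p{i}" for i in range(1, length + 1)]
    if "NCP" in cfg.blocks:
        names["NCP"] = [
            f"NCP_p{i}_b{b}" for i in range(1, length + 1) for b in (1, 2, 3)
        ]
    if "BIN" in cfg.blocks:
        names["BIN"] = [
            f"BIN_p{i}_{nt}" for i in range(1, length + 1) for nt in ALPHABET
        ]
    if "SCPDNC" in cfg.blocks:
        names["SCPDNC"] = [
            f"SCPDNC_{i}" for i in range(1, 17 + cfg.pse_lambda * table.n_indices)
        ]
    if "W2V" in cfg.blocks:
        names["W2V"] = [f"W2V_{i}" for i in range(1, cfg.embed_dim + 1)]
    return names


class FeatureMatrix:
    """Named feature columns x segments, with block provenance and labels."""

    def __init__(
        self,
        data: pd.DataFrame,
        block_map: dict[str, tuple[int, int]],
        labels: pd.Series | None = None,
    ):
        if data.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        self.data = data
        self.block_map = dict(block_map)
        self.labels = labels

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def block(self, name: str) -> pd.DataFrame:
        start, stop = self.block_map[name]
        return self.data.iloc[:, start:stop]

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.data.copy()
        out.insert(0, "id", self.data.index)
        if self.labels is not None:
            out.insert(1, "label", self.labels.to_numpy())
        out.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        raw = pd.read_csv(path)
        raw = raw.set_index("id")
        labels = None
        if "label" in raw.columns:
            labels = raw.pop("label").astype(int)
        block_map = _infer_block_map(list(raw.columns))
        return cls(raw, block_map, labels)


def _infer_block_map(columns: list[str]) -> dict[str, tuple[int, int]]:
    block_map: dict[str, tuple[int, int]] = {}
    for i, col in enumerate(columns):
        block = col.split("_", 1)[0]
        if block in block_map:
            start, stop = block_map[block]
            if stop != i:
                raise ValueError(f"block {block} is not contiguous at column {col}")
            block_map[block] = (start, i + 1)
        else:
            block_map[block] = (i, i + 1)
    return block_map


def encode_all(
    segments: SegmentSet,
    cfg: EncoderConfig | None = None,
    table: DinucleotidePropertyTable | None = None,
    model: Word2VecModel | None = None,
) -> FeatureMatrix:
    """Encode a segment set into the canonical concatenated feature matrix.

    With the default configuration on 41-nt segments the result has exactly
    808 columns in block order ENAC, CKSNAP, ANF, NCP, BIN, SCPDNC, W2V.
    The W2V block requires a trained embedding ``model``; drop "W2V" from
    ``cfg.blocks`` to encode without one.
    """
    cfg = cfg or EncoderConfig()
    table = table or DinucleotidePropertyTable.default()
    if "W2V" in cfg.blocks and model is None:
        raise ValueError(
            "W2V block requested but no embedding model given; "
            "call train_embedding first or drop 'W2V' from cfg.blocks"
        )
    if len(segments) == 0:
        raise ValueError("empty segment set")
    sequences = [s.sequence for s in segments]
    length = len(sequences[0])
    codes = _codes(sequences)

    parts: list[np.ndarray] = []
    block_map: dict[str, tuple[int, int]] = {}
    names = feature_names(cfg, length, table)
    offset = 0
    for blockname in cfg.blocks:
        if blockname == "ENAC":
            arr = enac_matrix(codes, cfg.enac_window)
        elif blockname == "CKSNAP":
            arr = cksnap_matrix(codes, cfg.cksnap_max_gap)
        elif blockname == "ANF":
            arr = anf_matrix(codes)
        elif blockname == "NCP":
            arr = ncp_matrix(codes)
        elif blockname == "BIN":
            arr = binary_matrix(codes)
        elif blockname == "SCPDNC":
            arr = scpsednc_matrix(codes, cfg.pse_lambda, cfg.pse_weight, table)
        else:  # W2V
            arr = word2vec_matrix(sequences, model)
        if arr.shape[1] != len(names[blockname]):
            raise AssertionError(
                f"{blockname}: {arr.shape[1]} columns vs {len(names[blockname])} names"
            )
        block_map[blockname] = (offset, offset + arr.shape[1])
        offset += arr.shape[1]
        parts.append(arr)

    data = pd.DataFrame(
        np.concatenate(parts, axis=1),
        index=pd.Index(segments.ids, name="id"),
        columns=[n for b in cfg.blocks for n in names[b]],
    )
    labels = None
    if all(lbl is not None for lbl in segments.labels):
        labels = pd.Series(segments.labels, index=data.index, dtype=int)
    return FeatureMatrix(data, block_map, labels)
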