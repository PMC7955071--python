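"""Sample entropy and variance features over the sub-band decomposition.

For each epoch, each of the two central derivations (C3-A2, C4-A1) is
decomposed into the five EEG sub-bands and two statistics are computed per
band-limited signal: the population variance and the sample entropy
SampEn(m, r) with m = 2 and r = 0.2 times the signal's own standard
deviation.  With two channels, five bands and two statistics this yields a
20-column feature matrix, laid out variance-first:

    var C3 (delta..beta), var C4 (delta..beta),
    sampen C3 (delta..beta), sampen C4 (delta..beta).

Sample entropy follows the Richman–Moorman convention: templates of length
m and m+1 are both drawn from i = 1..N-m, matches use the Chebyshev
distance, self-matches are excluded, and

    SampEn = -ln( B^{m+1}(r) / B^{m}(r) ).

A perfectly regular (constant) series gives 0; richer, noise-like signals
give larger values.  Because r scales with the signal's standard deviation,
SampEn is invariant under positive rescaling of the signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .io import EpochSet
from .subband import BandDefinition, DEFAULT_BANDS, DEFAULT_FILTER_ORDER, FilterBank

__all__ = [
    "SampEnParams",
    "FeatureColumn",
    "FeatureMatrix",
    "sample_entropy",
    "variance",
    "extract_features",
]


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: template length m and radius factor.

    The similarity radius is ``r = r_factor * std(x)``, computed from each
    band-limited signal's own standard deviation.
    """

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r_factor <= 0:
            raise ValueError(f"r_factor must be positive, got {self.r_factor}")


@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Count template pairs matching at length m (B) and m+1 (A).

    Pairs (i, j), i < j, over the N-m templates starting at 0..N-m-1;
    Chebyshev distance; self-matches excluded by construction.
    """
    n = x.shape[0]
    n_templates = n - m
    b = 0
    a = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return b, a


def sample_entropy(
    x: np.ndarray, params: SampEnParams = SampEnParams()
) -> float:
    """Sample entropy SampEn(m, r_factor*std(x)) of a 1-D series.

    Returns 0.0 for a constant series (every template matches every
    other at both lengths).  If no template pair matches at length m+1,
    the value is undefined (-ln 0); the Chon-style finite upper bound
    ``-ln(2 / ((N-m-1)(N-m)))`` is returned instead with a warning, so a
    single maximally irregular band signal cannot poison a feature matrix.
    """
    x = np.ascontiguousarray(x, dtype=np.float64).ravel()
    n = x.size
    m = params.m
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m} (need >= {m + 2})")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = params.r_factor * sd
    b, a = _sampen_counts(x, m, r)
    if a == 0 or b == 0:
        bound = -np.log(2.0 / ((n - m - 1) * (n - m)))
        warnings.warn(
            "no template matches at length m+1; returning the finite "
            f"upper bound {bound:.4f} instead of +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(bound)
    return float(-np.log(a / b))


def variance(x: np.ndarray) -> float:
    """Population variance (mean squared deviation, divide by N)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("variance of an empty series is undefined")
    return float(np.var(x))


@dataclass(frozen=True)
class FeatureColumn:
    """One column of the feature matrix: (statistic, channel, band)."""

    index: int  # 1-based position in the layout
    feature: str  # "variance" | "sample_entropy"
    channel: str  # short derivation label, e.g. "C3"
    band: str  # band name, e.g. "delta"

    @property
    def name(self) -> str:
        return f"{self.feature}__{self.channel}__{self.band}"


def _short_channel(name: str) -> str:
    return name.split("-")[0].strip()


def feature_layout(
    channel_names: tuple[str, ...],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> list[FeatureColumn]:
    """Column registry: variance blocks first, then sample entropy,
    each block ordered channel-major, band-minor."""
    cols: list[FeatureColumn] = []
    idx = 1
    for feat in ("variance", "sample_entropy"):
        for ch in channel_names:
            for b in bands:
                cols.append(FeatureColumn(idx, feat, _short_channel(ch), b.name))
                idx += 1
    return cols


@dataclass
class FeatureMatrix:
    """n_epochs x n_features matrix with a typed column registry."""

    values: np.ndarray
    columns: list[FeatureColumn]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column registry does not match values width")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length does not match rows")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[c.name for c in self.columns])
        df["label"] = [str(l) for l in self.labels]
        return df

    def to_csv(self, path: str | Path, params: SampEnParams | None = None) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        sidecar = {
            "columns": [asdict(c) for c in self.columns],
            "sampen_params": asdict(params) if params else None,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            columns = [FeatureColumn(**c) for c in meta["columns"]]
        else:
            columns = [
                FeatureColumn(i + 1, *c.split("__"))
                for i, c in enumerate(df.columns)
                if c != "label"
            ]
        labels = df["label"].to_numpy(dtype=object)
        values = df.drop(columns="label").to_numpy(dtype=float)
        return cls(values=values, columns=columns, labels=labels)


def extract_features(
    epochs: EpochSet,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    params: SampEnParams = SampEnParams(),
    filter_order: int = DEFAULT_FILTER_ORDER,
) -> FeatureMatrix:
    """Sub-band variance + sample-entropy features for every epoch.

    Rows preserve epoch order; columns follow :func:`feature_layout`
    (20 columns for the default 2-channel, 5-band configuration).
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    bank = FilterBank(epochs.fs, bands, filter_order)
    cols = feature_layout(epochs.channel_names, bands)
    n_ch, n_bands = len(epochs.channel_names), len(bands)
    out = np.empty((epochs.n_epochs, 2 * n_ch * n_bands), dtype=float)
    for e in range(epochs.n_epochs):
        filtered = [bank.apply(epochs.epochs[e, c]) for c in range(n_ch)]
        col = 0
        for c in range(n_ch):
            for b in bands:
                out[e, col] = variance(filtered[c][b.name])
                col += 1
        for c in range(n_ch):
            for b in bands:
                out[e, col] = sample_entropy(filtered[c][b.name], params)
                col += 1
    return FeatureMatrix(values=out, columns=cols, labels=epochs.labels.copy())
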