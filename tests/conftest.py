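"""Shared fixtures: small synthetic epoch sets and a minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from somnoband.synthetic import SyntheticConfig, generate, generate_feature_table


@pytest.fixture(scope="session")
def small_epochs():
    """15 short epochs (5 s) across the three classes; fast to featurize."""
    return generate(SyntheticConfig(n_per_class=5, epoch_len_s=5.0, seed=11))


@pytest.fixture(scope="session")
def feature_table():
    """Tabular 3-class feature matrix, 5 informative of 20 columns."""
    return generate_feature_table(n=150, effect_size=3.0, seed=7)


def write_minimal_edf(
    path: Path,
    channel_names: list[str],
    fs: int,
    data: np.ndarray,
    physical_range: tuple[float, float] = (-1000.0, 1000.0),
) -> Path:
    """Write a bare-bones EDF file (synthetic test fixture, built at runtime).

    ``data`` is (n_channels, n_samples) in "physical" units; samples are
    quantized to int16 over ``physical_range``.  One-second data records.
    """
    n_ch, n_samp = data.shape
    n_records = n_samp // fs
    assert n_records * fs == n_samp, "need whole seconds of data"
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        assert len(b) <= width, s
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X synthetic", 80),
            pad("X test recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(name, 16) for name in channel_names],
        [pad("AgAgCl electrode", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{pmin:g}", 8)] * n_ch,
        [pad(f"{pmax:g}", 8)] * n_ch,
        [pad(str(dmin), 8)] * n_ch,
        [pad(str(dmax), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(fs), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    for block in fields:
        header += b"".join(block)

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data - pmin) * scale + dmin), dmin, dmax).astype(
        "<i2"
    )
    body = b""
    for rec in range(n_records):
        for ch in range(n_ch):
            chunk = digital[ch, rec * fs : (rec + 1) * fs]
            body += struct.pack(f"<{fs}h", *chunk.tolist())
    path.write_bytes(header + body)
    return path
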