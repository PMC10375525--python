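"""Plain-text I/O: decay histograms, IRF profiles, lifetime-component tables."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from diskfret.synth import DecayComponentSet, DecayHistogram, InstrumentResponse

__all__ = [
    "HistogramParseError",
    "write_histogram",
    "read_histogram",
    "read_component_table",
    "components_from_row",
    "load_generator_config",
    "TABLE_COLUMNS",
]

#: Column layout of a lifetime-component table (one row per sample;
#: mono-exponential samples leave the short-component fields empty).
TABLE_COLUMNS = (
    "sample",
    "label",
    "tau_long_ns",
    "se_long",
    "tau_short_ns",
    "se_short",
    "short_amp_pct",
)


class HistogramParseError(ValueError):
    """Malformed histogram file; the message names the first bad line."""


def write_histogram(h: DecayHistogram, path) -> None:
    """Write a histogram as two-column text (time_ns, counts) with a
    commented header carrying bin width and total count."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# diskfret decay histogram\n")
        fh.write(f"# bin_width_ns = {h.bin_width!r}\n")
        fh.write(f"# total_counts = {h.total_counts}\n")
        fh.write("# time_ns\tcounts\n")
        for t, c in zip(h.times, h.counts):
            fh.write(f"{float(t)!r}\t{int(c)}\n")


def read_histogram(path) -> DecayHistogram:
    """Read a histogram written by :func:`write_histogram`.

    Validates integer non-negative counts, a uniform time axis, and
    agreement between the header total and the column sum; raises
    :class:`HistogramParseError` naming the first offending line.
    """
    path = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    counts: list[int] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    header[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise HistogramParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                t = float(parts[0])
            except ValueError:
                raise HistogramParseError(
                    f"{path}:{lineno}: non-numeric time {parts[0]!r}"
                ) from None
            try:
                c = int(parts[1])
            except ValueError:
                raise HistogramParseError(
                    f"{path}:{lineno}: non-integer count {parts[1]!r}"
                ) from None
            if c < 0:
                raise HistogramParseError(
                    f"{path}:{lineno}: negative count {c}"
                )
            times.append(t)
            counts.append(c)
    if len(times) < 2:
        raise HistogramParseError(f"{path}: fewer than 2 data rows")
    t_arr = np.asarray(times)
    steps = np.diff(t_arr)
    h = steps[0]
    bad = np.flatnonzero(~np.isclose(steps, h, rtol=1e-9, atol=1e-12))
    if bad.size:
        raise HistogramParseError(
            f"{path}: non-uniform time axis near row {int(bad[0]) + 2}"
        )
    if "bin_width_ns" in header:
        declared = float(header["bin_width_ns"])
        if not math.isclose(declared, h, rel_tol=1e-9):
            raise HistogramParseError(
                f"{path}: header bin_width_ns {declared} does not match "
                f"time axis step {h}"
            )
    total = int(np.sum(counts))
    if "total_counts" in header and int(header["total_counts"]) != total:
        raise HistogramParseError(
            f"{path}: header total_counts {header['total_counts']} "
            f"does not match column sum {total}"
        )
    return DecayHistogram(bin_width=float(h), counts=np.asarray(counts))


def read_component_table(path) -> pd.DataFrame:
    """Read a delimited lifetime-component table.

    Expected tab-separated columns: sample, label, tau_long_ns, se_long,
    tau_short_ns, se_short, short_amp_pct.  Empty short-component fields
    denote a mono-exponential sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"component table missing columns {sorted(missing)}")
    if (df["tau_long_ns"] <= 0).any():
        bad = df.loc[df["tau_long_ns"] <= 0, "sample"].iloc[0]
        raise ValueError(f"non-positive long lifetime for sample {bad}")
    has_short = df["tau_short_ns"].notna()
    if (df.loc[has_short, "tau_short_ns"] <= 0).any():
        bad = df.loc[has_short & (df["tau_short_ns"] <= 0), "sample"].iloc[0]
        raise ValueError(f"non-positive short lifetime for sample {bad}")
    pct = df.loc[has_short, "short_amp_pct"]
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("short_amp_pct must lie in [0, 100]")
    return df


def components_from_row(row) -> DecayComponentSet:
    """Build a decay model from one component-table row.

    The short-component percent amplitude fixes the amplitude split;
    lifetimes are stored sorted ascending (short first).
    """
    tau_long = float(row["tau_long_ns"])
    tau_short = row.get("tau_short_ns")
    if tau_short is None or (isinstance(tau_short, float) and math.isnan(tau_short)):
        return DecayComponentSet(components=((1.0, tau_long),))
    frac_short = float(row["short_amp_pct"]) / 100.0
    return DecayComponentSet(
        components=(
            (frac_short, float(tau_short)),
            (1.0 - frac_short, tau_long),
        )
    )


def load_generator_config(path) -> dict:
    """Load a plain-text (YAML) simulation config.

    Recognized keys: ``components`` (list of ``[amplitude, lifetime_ns]``
    pairs), ``background_fraction``, ``fwhm_ps``, ``t0_ns``,
    ``total_counts``, ``seed``, ``bin_width_ns``, ``n_bins``.  Returns a
    dict with ``model`` (:class:`DecayComponentSet`), ``irf``
    (:class:`InstrumentResponse`) and the remaining scalars.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "components" not in raw:
        raise ValueError("generator config needs a 'components' list")
    comps = tuple(
        sorted(((float(a), float(t)) for a, t in raw["components"]), key=lambda p: p[1])
    )
    model = DecayComponentSet(
        components=comps,
        background_fraction=float(raw.get("background_fraction", 0.0)),
    )
    irf = InstrumentResponse(
        fwhm_ps=float(raw.get("fwhm_ps", 150.0)),
        t0_ns=float(raw.get("t0_ns", 2.0)),
    )
    return {
        "model": model,
        "irf": irf,
        "total_counts": int(raw.get("total_counts", 1_000_000)),
        "seed": int(raw.get("seed", 0)),
        "bin_width_ns": float(raw.get("bin_width_ns", 0.016)),
        "n_bins": int(raw.get("n_bins", 4096)),
    }
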