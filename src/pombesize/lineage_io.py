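"""Lineage dataset container, CSV round-trip, and synthetic-data generation.

The on-disk format is a long-format CSV with columns ``lineage_id, time_h,
size_um, generation_index, is_division_sample`` preceded by ``#``-prefixed
``key=value`` metadata lines.  ``is_division_sample`` marks the first sample
of a new generation (the sample just after a division event).

The synthetic generator emulates published microfluidic lineage data of
fission yeast: sizes sampled every 3 minutes, tens of generations per
lineage, sizes in micrometres, with optional multiplicative log-normal
measurement noise (default CV 2%).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import GrowthParams
from .simulate import (
    GenerationSummary,
    LineageTimecourse,
    sample_timecourse,
    simulate_lineage,
)

__all__ = [
    "LineageDataset",
    "write_lineages",
    "read_lineages",
    "generate_dataset",
    "extract_generations",
    "extract_ratios",
]

COLUMNS = ["lineage_id", "time_h", "size_um", "generation_index", "is_division_sample"]


@dataclass
class LineageDataset:
    """A collection of lineage time courses sharing one sampling interval."""

    lineages: list[LineageTimecourse]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lineages)

    @property
    def dt_h(self) -> float:
        return float(self.metadata.get("dt_h", np.diff(self.lineages[0].time_h).mean()))


def write_lineages(dataset: LineageDataset, path: str | Path) -> None:
    """Write the long-format CSV with '#' metadata header lines."""
    buf = io.StringIO()
    for k, v in dataset.metadata.items():
        buf.write(f"# {k}={v}\n")
    frames = []
    for tc in dataset.lineages:
        n = len(tc.time_h)
        is_div = np.zeros(n, dtype=bool)
        if n:
            is_div[1:] = np.diff(tc.generation_index) > 0
        frames.append(
            pd.DataFrame(
                {
                    "lineage_id": tc.lineage_id,
                    "time_h": tc.time_h,
                    "size_um": tc.size_um,
                    "generation_index": tc.generation_index,
                    "is_division_sample": is_div.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(buf, index=False, float_format="%.12g")
    Path(path).write_text(buf.getvalue())


def read_lineages(path: str | Path) -> LineageDataset:
    """Read the lineage CSV; inverse of :func:`write_lineages` to 1e-9."""
    text = Path(path).read_text().splitlines()
    metadata: dict = {}
    body_start = 0
    for i, line in enumerate(text):
        if line.startswith("#"):
            k, _, v = line.lstrip("# ").partition("=")
            try:
                metadata[k] = float(v)
            except ValueError:
                metadata[k] = v
            body_start = i + 1
        else:
            break
    df = pd.read_csv(io.StringIO("\n".join(text[body_start:])))
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df[COLUMNS[:4]].isna().any().any():
        raise ValueError("malformed rows: NaN in required columns")
    lineages = []
    n_empty = 0
    for lid, sub in df.groupby("lineage_id", sort=True):
        if len(sub) < 2:
            n_empty += 1
            continue
        t = sub["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone time in lineage {lid}")
        gi = sub["generation_index"].to_numpy(dtype=int)
        sizes = sub["size_um"].to_numpy(dtype=float)
        # reconstruct division event times from generation boundaries
        div_idx = np.where(np.diff(gi) > 0)[0] + 1
        div_times = t[div_idx] if len(div_idx) else np.array([])
        lineages.append(
            LineageTimecourse(
                time_h=t, size_um=sizes, generation_index=gi,
                division_times=div_times, lineage_id=int(lid),
            )
        )
    if n_empty:
        warnings.warn(f"skipped {n_empty} empty lineages", stacklevel=2)
    ds = LineageDataset(lineages=lineages, metadata=metadata)
    ds.metadata.setdefault("n_skipped_empty", n_empty)
    return ds


def generate_dataset(
    params: GrowthParams,
    n_lineages: int,
    generations: int,
    dt_min: float = 3.0,
    noise_cv: float = 0.02,
    seed: int | None = None,
    burn_in: int = 50,
) -> LineageDataset:
    """Simulate a synthetic lineage dataset.

    Each lineage is an independent stationary chain of ``generations``
    generations (after ``burn_in`` discarded ones) sampled every ``dt_min``
    minutes with multiplicative log-normal measurement noise of coefficient
    of variation ``noise_cv``.  Deterministic under ``seed``.
    """
    if dt_min <= 0:
        raise ValueError("need dt_min > 0")
    dt_h = dt_min / 60.0
    root = np.random.default_rng(seed)
    children = root.spawn(n_lineages)
    lineages = []
    for lid, rng in enumerate(children):
        gens = simulate_lineage(params, generations, rng, burn_in=burn_in)
        tc = sample_timecourse(gens, dt_h, noise_cv=noise_cv,
                               rng=rng if noise_cv > 0 else None, lineage_id=lid)
        lineages.append(tc)
    meta = {"dt_h": dt_h, "noise_cv": noise_cv, "n_lineages": n_lineages,
            "generations": generations, "seed": "" if seed is None else seed}
    meta.update({f"param_{k}": v for k, v in params.to_dict().items()})
    return LineageDataset(lineages=lineages, metadata=meta)


def extract_generations(tc: LineageTimecourse) -> list[GenerationSummary]:
    """Split a time course at division markers into per-generation summaries.

    Birth size is the first sample of a generation and division size the
    last; the partition ratio attached to generation ``k`` is
    ``V_b(k+1)/V_d(k)``.  Phase durations and septation size are not resolved
    here (use the three-stage fit); the corresponding fields are NaN.
    """
    gi = tc.generation_index
    out: list[GenerationSummary] = []
    bounds = np.where(np.diff(gi) > 0)[0]
    starts = np.concatenate([[0], bounds + 1])
    ends = np.concatenate([bounds, [len(gi) - 1]])
    nan = float("nan")
    for j, (s, e) in enumerate(zip(starts, ends)):
        vb = float(tc.size_um[s])
        vd = float(tc.size_um[e])
        T = float(tc.time_h[e] - tc.time_h[s])
        r = float(tc.size_um[ends[j] + 1] / vd) if j < len(starts) - 1 else nan
        out.append(
            GenerationSummary(
                V_b=vb, V_s=nan, V_d=vd, T=T,
                T_elong=nan, T_sept=nan, T_reshape=nan,
                Delta0=nan, Delta1=nan, R=r,
            )
        )
    return out


def extract_ratios(dataset: LineageDataset) -> np.ndarray:
    """All partition ratios V_b(k+1)/V_d(k) pooled across lineages."""
    ratios = []
    for tc in dataset.lineages:
        gens = extract_generations(tc)
        ratios.extend(g.R for g in gens[:-1])
    return np.asarray(ratios, dtype=float)
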