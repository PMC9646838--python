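"""Cohort manifests, stratified splits, configuration and logging.

Manifests are UTF-8 TSV files with a header row; empty string means missing.
Columns: ``slide_id`` (unique), ``path``, optional ``label``, optional
``time``/``event`` (present together), optional ``n_patches`` and ``split``
(one of train/val/test).  All writes are atomic (temp file then rename).
"""

from __future__ import annotations

import logging
import os
import sys
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortManifest",
    "read_manifest",
    "write_manifest",
    "stratified_split",
    "atomic_write_text",
    "load_config",
    "setup_logging",
    "SPLITS",
]

SPLITS = ("train", "val", "test")

_COLUMNS = ("slide_id", "path", "label", "time", "event", "n_patches", "split")


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text via a temp file + rename so readers never see partial files."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


@dataclass
class CohortManifest:
    """Validated slide table; row order is preserved from the source file."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if "slide_id" not in df.columns:
            raise ValueError("manifest must have a slide_id column")
        dup = df["slide_id"][df["slide_id"].duplicated()]
        if len(dup):
            row = int(df.index[df["slide_id"] == dup.iloc[0]][1]) + 2
            raise ValueError(f"duplicate slide_id {dup.iloc[0]!r} at line {row}")
        if "split" in df.columns:
            bad = df["split"].dropna()
            bad = bad[(bad != "") & ~bad.isin(SPLITS)]
            if len(bad):
                row = int(bad.index[0]) + 2
                raise ValueError(f"unknown split {bad.iloc[0]!r} at line {row}; "
                                 f"allowed: {SPLITS}")
        has_time = df["time"].notna() if "time" in df.columns \
            else pd.Series(False, index=df.index)
        has_event = df["event"].notna() if "event" in df.columns \
            else pd.Series(False, index=df.index)
        orphan = has_time ^ has_event
        if orphan.any():
            row = int(df.index[orphan][0]) + 2
            raise ValueError(f"time and event must be present together "
                             f"(line {row})")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, split: str) -> "CohortManifest":
        if "split" not in self.df.columns:
            raise ValueError("manifest has no split column; run stratified_split")
        return CohortManifest(self.df[self.df["split"] == split].reset_index(drop=True))


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t", dtype={"slide_id": str, "path": str,
                                            "split": str},
                     keep_default_na=True, na_values=[""])
    return CohortManifest(df)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    df = manifest.df
    cols = [c for c in _COLUMNS if c in df.columns] \
        + [c for c in df.columns if c not in _COLUMNS]
    out = df[cols].copy()
    # integer-valued columns round-trip without a trailing .0
    for col in ("label", "event", "n_patches"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else str(int(v)))
    text = out.to_csv(sep="\t", index=False, na_rep="")
    atomic_write_text(path, text)


def _split_names(n: int) -> list[str]:
    if n == 1:
        return ["train"]
    if n == 2:
        return ["train", "test"]
    if n == 3:
        return ["train", "val", "test"]
    raise ValueError("fractions must have 1-3 entries")


def stratified_split(manifest: CohortManifest, fractions: tuple[float, ...],
                     seed: int, by: str = "label") -> CohortManifest:
    """Assign train/val/test splits with per-class proportional allocation.

    Integer quotas per class follow the largest-remainder rule; members are
    shuffled by the seeded generator before being dealt into consecutive
    quota blocks, so the same seed reproduces the same assignment.  Slides
    with no value in ``by`` form their own stratum.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    names = _split_names(len(fractions))
    df = manifest.df.copy()
    strata = df[by].fillna("__none__") if by in df.columns \
        else pd.Series("__none__", index=df.index)
    rng = np.random.default_rng(seed)
    split_col = pd.Series("", index=df.index, dtype=object)
    for value in sorted(strata.unique(), key=str):
        idx = df.index[strata == value].to_numpy()
        if len(idx) < len(fractions):
            raise ValueError(f"stratum {value!r} has {len(idx)} members for "
                             f"{len(fractions)} splits")
        quota = np.floor(np.array(fractions) * len(idx)).astype(int)
        rem = len(idx) - quota.sum()
        if rem:
            frac_part = np.array(fractions) * len(idx) - quota
            for j in np.argsort(-frac_part, kind="stable")[:rem]:
                quota[j] += 1
        order = rng.permutation(len(idx))
        start = 0
        for name, q in zip(names, quota):
            split_col.loc[idx[order[start:start + q]]] = name
            start += q
    df["split"] = split_col
    return CohortManifest(df)


def load_config(path: str | Path) -> dict:
    """Load the flat ``experiment:`` section of a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    exp = data.get("experiment", data)
    if not isinstance(exp, dict):
        raise ValueError("config must contain a mapping under 'experiment'")
    return exp


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
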