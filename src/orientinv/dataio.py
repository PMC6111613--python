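"""Readers and writers for the on-disk dataset layout.

The directory layout mirrors the public daily/sports-activities recording
campaign: one plain-text file per 5-s segment,

    <root>/a01/p1/s01.txt        activity a01..aKK, subject p1..pP, segment s01..sSS

each file comma-separated with N rows (time samples) and 45 columns.  The
column dialect is unit-major: five units in the order torso, right arm, left
arm, right leg, left leg, and within each unit acc x/y/z, gyro x/y/z, mag
x/y/z.  The public description does not pin the column order down, so the
dialect here is a documented convention that can be overridden when loading.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SyntheticDataset
from .transforms import UnitSegment

UNIT_NAMES = ("torso", "right_arm", "left_arm", "right_leg", "left_leg")
N_COLUMNS = 45


class DatasetFormatError(ValueError):
    """A segment file does not follow the expected dialect."""


def write_segment_file(path, table: np.ndarray) -> None:
    """Write one (N, 9 * units) segment table as comma-separated text.

    The canonical dialect has 45 columns (five units); smaller unit counts
    are accepted so down-scaled synthetic trees use the same format.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] % 9 != 0 or table.shape[1] == 0:
        raise ValueError("expected an (N, 9 * units) table")
    np.savetxt(path, table, delimiter=",", fmt="%.17g")


def read_segment_file(path, rate: float = 25.0,
                      n_units: int = 5) -> list[UnitSegment]:
    """Read one segment file into one :class:`UnitSegment` per unit.

    Raises :class:`DatasetFormatError` naming the offending row on malformed
    input (wrong column count or non-numeric fields).
    """
    n_columns = 9 * n_units
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != n_columns:
                raise DatasetFormatError(
                    f"{path}: row {lineno} has {len(parts)} columns, "
                    f"expected {n_columns}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise DatasetFormatError(
                    f"{path}: row {lineno} contains a non-numeric field") from exc
    table = np.array(rows)
    segs = []
    for u in range(n_units):
        block = table[:, 9 * u: 9 * (u + 1)]
        segs.append(UnitSegment(acc=block[:, 0:3], gyro=block[:, 3:6],
                                mag=block[:, 6:9], rate=rate, unit=u))
    return segs


@dataclass
class DatasetIndex:
    """Map (activity, subject, segment) -> file path, plus the dialect."""

    root: Path
    files: dict  # (activity, subject, segment) 0-based -> Path
    n_classes: int
    n_subjects: int
    n_segments: int
    rate: float = 25.0
    n_units: int = 5


def index_dataset(root, rate: float = 25.0) -> DatasetIndex:
    """Scan a dataset tree and index every segment file present."""
    root = Path(root)
    files = {}
    n_a = n_p = n_s = 0
    for a_dir in sorted(root.glob("a[0-9][0-9]")):
        a = int(a_dir.name[1:]) - 1
        for p_dir in sorted(a_dir.glob("p[0-9]*")):
            p = int(p_dir.name[1:]) - 1
            for f in sorted(p_dir.glob("s[0-9][0-9]*.txt")):
                s = int(f.stem[1:]) - 1
                files[(a, p, s)] = f
                n_a, n_p, n_s = max(n_a, a + 1), max(n_p, p + 1), max(n_s, s + 1)
    if not files:
        raise DatasetFormatError(f"no segment files found under {root}")
    return DatasetIndex(root, files, n_a, n_p, n_s, rate=rate)


def write_dataset(ds: SyntheticDataset, root) -> None:
    """Write an in-memory dataset in the directory/CSV dialect above."""
    root = Path(root)
    S, U, N, _ = ds.data.shape
    for i in range(S):
        a, p, s = ds.activities[i], ds.subjects[i], ds.segments[i]
        d = root / f"a{a + 1:02d}" / f"p{p + 1}"
        d.mkdir(parents=True, exist_ok=True)
        write_segment_file(d / f"s{s + 1:02d}.txt",
                           ds.data[i].transpose(1, 0, 2).reshape(N, U * 9))


def load_dataset(root, rate: float = 25.0, n_units: int | None = None,
                 stationary_classes=(0, 1, 2, 3)) -> SyntheticDataset:
    """Load a dataset tree into the in-memory container (no ground truth).

    The unit count is inferred from the column count (9 channels per unit)
    unless given explicitly.
    """
    index = index_dataset(root, rate=rate)
    # subject-major ordering, matching the simulator's in-memory layout
    keys = sorted(index.files, key=lambda k: (k[1], k[0], k[2]))
    tables = []
    for key in keys:
        t = np.loadtxt(index.files[key], delimiter=",", ndmin=2)
        if n_units is None:
            n_units = t.shape[1] // 9
        if t.shape[1] != 9 * n_units or t.shape[1] == 0:
            raise DatasetFormatError(f"{index.files[key]}: expected "
                                     f"{9 * n_units} columns, found {t.shape[1]}")
        tables.append(t)
    n = tables[0].shape[0]
    data = np.stack(tables).reshape(len(keys), n, n_units, 9).transpose(0, 2, 1, 3)
    acts = np.array([k[0] for k in keys])
    subs = np.array([k[1] for k in keys])
    segs = np.array([k[2] for k in keys])
    stationary = np.zeros(index.n_classes, dtype=bool)
    stationary[[c for c in stationary_classes if c < index.n_classes]] = True
    return SyntheticDataset(data=data, subjects=subs, activities=acts,
                            segments=segs, quats=None, rate=rate,
                            stationary=stationary)


def write_features_tsv(path, X: np.ndarray, subjects, activities,
                       segments) -> None:
    """Feature table with subject/activity/segment keys and f1..fD columns."""
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=[f"f{i + 1}" for i in range(X.shape[1])])
    df.insert(0, "segment", np.asarray(segments))
    df.insert(0, "activity", np.asarray(activities))
    df.insert(0, "subject", np.asarray(subjects))
    df.to_csv(path, sep="\t", index=False)
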