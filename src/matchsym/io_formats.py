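"""Landmark data containers, TPS file I/O and design filtering.

Datasets are collections of digitized 2D landmark configurations keyed by
individual, anchor type (dorsal/ventral), body side (left/right) and
digitization replicate.  The analyses downstream assume a balanced
individual x side design with a fixed number of replicates per cell, so
this module also provides the filter that retains only individuals with a
complete set of configurations.

TPS files carry no structured metadata, so specimen identity is encoded in
the ID field as ``<individual>_<D|V>_<L|R>_r<k>`` (e.g. ``ind07_D_L_r2``).
Alternatively a sidecar CSV manifest with columns
``individual_id,host_id,anchor_type,side,replicate,specimen_index`` may be
supplied; manifest rows are matched to TPS blocks by 0-based block index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANCHOR_TYPES = ("dorsal", "ventral")
SIDES = ("left", "right")

_ANCHOR_CODE = {"D": "dorsal", "V": "ventral"}
_SIDE_CODE = {"L": "left", "R": "right"}
_CODE_ANCHOR = {v: k for k, v in _ANCHOR_CODE.items()}
_CODE_SIDE = {v: k for k, v in _SIDE_CODE.items()}


class TPSParseError(ValueError):
    """Raised when a TPS file is malformed."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """An ordered set of 2D landmark coordinates.

    Parameters
    ----------
    points : (LM, 2) float array
        Cartesian coordinates in arbitrary (but consistent) length units.
    point_roles : tuple of str
        Per-point tag, ``"landmark"`` or ``"semilandmark"``.  Semilandmarks
        are points placed by a rule along outline curves; they are treated
        as fixed points throughout.
    """

    points: np.ndarray
    point_roles: tuple[str, ...] = ()

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (LM, 2), got {pts.shape}")
        if pts.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "points", pts)
        roles = tuple(self.point_roles) if self.point_roles else tuple(
            "landmark" for _ in range(pts.shape[0])
        )
        if len(roles) != pts.shape[0]:
            raise ValueError("point_roles length must equal number of points")
        bad = set(roles) - {"landmark", "semilandmark"}
        if bad:
            raise ValueError(f"unknown point roles: {bad}")
        object.__setattr__(self, "point_roles", roles)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def flat(self) -> np.ndarray:
        """Coordinates flattened to a 2*LM vector (x1, y1, x2, y2, ...)."""
        return self.points.ravel().copy()


@dataclass(frozen=True)
class SpecimenRecord:
    """One digitized configuration with its design metadata."""

    individual_id: str
    anchor_type: str
    side: str
    replicate: int
    config: LandmarkConfiguration
    host_id: str | None = None

    def __post_init__(self):
        if self.anchor_type not in ANCHOR_TYPES:
            raise ValueError(f"anchor_type must be one of {ANCHOR_TYPES}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if not (isinstance(self.replicate, (int, np.integer)) and self.replicate >= 1):
            raise ValueError("replicate must be a positive integer")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.individual_id, self.anchor_type, self.side, self.replicate)


@dataclass
class LandmarkDataset:
    """A collection of specimen records sharing a landmark scheme.

    Within one anchor type all configurations must have the same number of
    points in the same order.  The dataset is *balanced* for an anchor type
    when every retained individual has both sides times all replicates.
    """

    records: list[SpecimenRecord] = field(default_factory=list)

    def __post_init__(self):
        self._check_consistent()

    def _check_consistent(self):
        by_anchor: dict[str, int] = {}
        seen: set[tuple[str, str, str, int]] = set()
        for rec in self.records:
            lm = rec.config.n_points
            prev = by_anchor.setdefault(rec.anchor_type, lm)
            if prev != lm:
                raise ValueError(
                    f"inconsistent point count for anchor_type={rec.anchor_type}: "
                    f"{prev} vs {lm}"
                )
            if rec.key in seen:
                raise ValueError(f"duplicate record key {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, anchor_type: str) -> "LandmarkDataset":
        return LandmarkDataset(
            [r for r in self.records if r.anchor_type == anchor_type]
        )

    def individuals(self, anchor_type: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if anchor_type is None or r.anchor_type == anchor_type:
                seen.setdefault(r.individual_id, None)
        return list(seen)

    def n_replicates(self, anchor_type: str | None = None) -> int:
        reps = {
            r.replicate
            for r in self.records
            if anchor_type is None or r.anchor_type == anchor_type
        }
        return max(reps) if reps else 0

    def n_points(self, anchor_type: str) -> int:
        for r in self.records:
            if r.anchor_type == anchor_type:
                return r.config.n_points
        raise KeyError(f"no records with anchor_type={anchor_type}")

    def get(self, individual_id, anchor_type, side, replicate) -> SpecimenRecord:
        for r in self.records:
            if r.key == (individual_id, anchor_type, side, replicate):
                return r
        raise KeyError((individual_id, anchor_type, side, replicate))

    def is_balanced(self, anchor_type: str) -> bool:
        """True iff every individual has both sides x all replicates."""
        sub = [r for r in self.records if r.anchor_type == anchor_type]
        if not sub:
            return False
        reps = sorted({r.replicate for r in sub})
        if reps != list(range(1, len(reps) + 1)):
            return False
        keys = {(r.individual_id, r.side, r.replicate) for r in sub}
        for ind in {r.individual_id for r in sub}:
            for side in SIDES:
                for rep in reps:
                    if (ind, side, rep) not in keys:
                        return False
        return True


def _encode_id(rec: SpecimenRecord) -> str:
    return (
        f"{rec.individual_id}_{_CODE_ANCHOR[rec.anchor_type]}"
        f"_{_CODE_SIDE[rec.side]}_r{rec.replicate}"
    )


_ID_RE = re.compile(r"^(?P<ind>.+)_(?P<anchor>[DV])_(?P<side>[LR])_r(?P<rep>\d+)$")


def _decode_id(id_field: str, block_no: int) -> dict:
    m = _ID_RE.match(id_field.strip())
    if m is None:
        raise TPSParseError(
            f"block {block_no}: ID field {id_field!r} does not follow "
            "'<individual>_<D|V>_<L|R>_r<k>'"
        )
    return {
        "individual_id": m["ind"],
        "anchor_type": _ANCHOR_CODE[m["anchor"]],
        "side": _SIDE_CODE[m["side"]],
        "replicate": int(m["rep"]),
    }


def read_tps(path, manifest: str | Path | None = None) -> LandmarkDataset:
    """Read a TPS landmark file into a :class:`LandmarkDataset`.

    Each ``LM=`` block yields one :class:`SpecimenRecord`.  A ``SCALE=``
    line, when present, is applied multiplicatively to the block's
    coordinates.  Metadata comes from the ID field naming convention, or
    from *manifest* (CSV matched to blocks by ``specimen_index``).
    """
    path = Path(path)
    text = path.read_text()
    blocks = _split_blocks(text)
    if not blocks:
        raise TPSParseError(f"{path}: no LM= blocks found")

    manifest_rows: dict[int, dict] | None = None
    if manifest is not None:
        mf = pd.read_csv(manifest, dtype={"individual_id": str, "host_id": str})
        required = {"individual_id", "anchor_type", "side", "replicate", "specimen_index"}
        missing = required - set(mf.columns)
        if missing:
            raise TPSParseError(f"manifest missing columns: {sorted(missing)}")
        manifest_rows = {int(row.specimen_index): row._asdict() for row in mf.itertuples()}

    records = []
    for block_no, blk in enumerate(blocks):
        lm_declared, coords, meta = blk
        if coords.shape[0] != lm_declared:
            raise TPSParseError(
                f"block {block_no}: declared LM={lm_declared} but found "
                f"{coords.shape[0]} coordinate rows"
            )
        if "SCALE" in meta:
            coords = coords * float(meta["SCALE"])
        if manifest_rows is not None:
            if block_no not in manifest_rows:
                raise TPSParseError(f"block {block_no}: no manifest row")
            row = manifest_rows[block_no]
            info = {
                "individual_id": str(row["individual_id"]),
                "anchor_type": str(row["anchor_type"]),
                "side": str(row["side"]),
                "replicate": int(row["replicate"]),
            }
            host = row.get("host_id")
            host = None if host is None or (isinstance(host, float) and np.isnan(host)) else str(host)
        elif "ID" in meta:
            info = _decode_id(meta["ID"], block_no)
            host = None
        else:
            raise TPSParseError(f"block {block_no}: missing ID field and no manifest")
        records.append(
            SpecimenRecord(config=LandmarkConfiguration(coords), host_id=host, **info)
        )
    return LandmarkDataset(records)


def _split_blocks(text: str):
    blocks = []
    cur = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"^LM\s*=\s*(\d+)$", line, flags=re.IGNORECASE)
        if m:
            if cur is not None:
                blocks.append(_finish_block(cur))
            cur = {"lm": int(m.group(1)), "coords": [], "meta": {}}
            continue
        if cur is None:
            raise TPSParseError(f"content before first LM= line: {line!r}")
        kv = re.match(r"^([A-Za-z]+)\s*=\s*(.*)$", line)
        if kv:
            cur["meta"][kv.group(1).upper()] = kv.group(2)
        else:
            parts = line.split()
            if len(parts) != 2:
                raise TPSParseError(f"bad coordinate line: {line!r}")
            cur["coords"].append((float(parts[0]), float(parts[1])))
    if cur is not None:
        blocks.append(_finish_block(cur))
    return blocks


def _finish_block(cur):
    coords = np.array(cur["coords"], dtype=float).reshape(-1, 2)
    return cur["lm"], coords, cur["meta"]


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write a dataset as TPS text.

    Coordinates are written post-scale to 17 significant digits (so a
    read/write round-trip is bit-exact) and no SCALE line is emitted.
    """
    if len(dataset) == 0:
        raise ValueError("cannot write an empty dataset")
    path = Path(path)
    lines = []
    for rec in dataset:
        lines.append(f"LM={rec.config.n_points}")
        for x, y in rec.config.points:
            lines.append(f"{float(x)!r} {float(y)!r}")
        lines.append(f"ID={_encode_id(rec)}")
    path.write_text("\n".join(lines) + "\n")


def filter_complete_pairs(
    dataset: LandmarkDataset, anchor_type: str, verbose: bool = False
) -> LandmarkDataset:
    """Retain only individuals with both sides x all replicates.

    The replicate count R is the maximum replicate index present for the
    anchor type; an individual is complete when all 2*R cells are present.
    The returned dataset contains only *anchor_type* records and satisfies
    the balanced-design invariant.
    """
    if anchor_type not in ANCHOR_TYPES:
        raise ValueError(f"anchor_type must be one of {ANCHOR_TYPES}")
    sub = [r for r in dataset if r.anchor_type == anchor_type]
    if not sub:
        raise ValueError(f"no records with anchor_type={anchor_type}")
    n_rep = max(r.replicate for r in sub)
    have: dict[str, set] = {}
    for r in sub:
        have.setdefault(r.individual_id, set()).add((r.side, r.replicate))
    needed = {(s, k) for s in SIDES for k in range(1, n_rep + 1)}
    complete = {ind for ind, cells in have.items() if needed <= cells}
    dropped = set(have) - complete
    if not complete:
        raise ValueError(
            f"no individual has a complete set of {len(needed)} "
            f"configurations for anchor_type={anchor_type}"
        )
    if verbose:
        print(
            f"{anchor_type}: retained {len(complete)} individuals, "
            f"dropped {len(dropped)}"
        )
    kept = [
        r
        for r in sub
        if r.individual_id in complete and (r.side, r.replicate) in needed
    ]
    out = LandmarkDataset(kept)
    assert out.is_balanced(anchor_type)
    return out
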