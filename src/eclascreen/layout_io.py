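"""GPR-dialect spot tables and the array-layout data model.

A reverse-phase lysate array is described at two levels:

* an :class:`ArrayScan` — every spot of one slide scanned under one assay
  condition (detection antibody, experiment vs secondary-only blank, batch),
  carrying the scanner's per-spot foreground/background medians and quality
  flags; and
* an :class:`ArrayLayout` — the print design mapping grid positions
  ``(block, row, column)`` to clone identities and control roles.  Every
  lysate clone is printed in duplicate, and the bottom row of each block
  holds the control spots (WT lysate, lysis buffer, BSA, poly-L-lysine,
  Protein A, anti-human antibody, and a fluorescent landmark).

Scans are read from and written to a tab-separated ATF/GPR dialect: an
``ATF\\t1.0`` magic line, a header-count line, quoted ``key=value`` header
records (assay metadata and grid geometry), a quoted column-name row, then
one data line per spot.  Columns are ``Block``, ``Row``, ``Column``,
``Name``, ``F635 Median``, ``B635 Median`` and ``Flags``; grid coordinates
are 1-based.  Control roles are resolved on read by exact name match against
a control vocabulary; any other name is a lysate clone.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CapacityError, FormatError, IntegrityError

__all__ = [
    "Role",
    "ANTIBODIES",
    "CONDITIONS",
    "DEFAULT_CONTROL_VOCABULARY",
    "DEFAULT_CONTROL_ROW",
    "SpotRecord",
    "ArrayScan",
    "ArrayLayout",
    "read_gpr",
    "write_gpr",
    "build_layout",
    "layout_from_scan",
    "read_manifest",
]


class Role(str, Enum):
    """What a printed spot physically is."""

    LYSATE = "lysate"
    WT_LYSATE = "wt_lysate"
    BUFFER = "buffer"
    BSA = "bsa"
    POLY_LYSINE = "poly_lysine"
    PROTEIN_A = "protein_a"
    ANTIHUMAN = "antihuman"
    LANDMARK = "landmark"


#: Detection channels. ``none`` marks a scan with no primary antibody track.
ANTIBODIES = ("pTyr100", "PY20", "antiHis", "NHS_ester", "none")

#: Assay conditions. ``control_no_primary`` = secondary-antibody-only blank.
CONDITIONS = ("experiment", "control_no_primary", "plus_ATP", "minus_ATP")

#: Spot names that resolve to control roles on read (exact match).
DEFAULT_CONTROL_VOCABULARY: Mapping[str, Role] = {
    "WT": Role.WT_LYSATE,
    "Buffer": Role.BUFFER,
    "BSA": Role.BSA,
    "Poly-L-Lysine": Role.POLY_LYSINE,
    "ProteinA": Role.PROTEIN_A,
    "AntiHuman": Role.ANTIHUMAN,
    "Landmark": Role.LANDMARK,
}

ROLE_DEFAULT_NAMES: Mapping[Role, str] = {
    role: name for name, role in DEFAULT_CONTROL_VOCABULARY.items()
}

#: One control row per block, printed at the bottom of the block.
DEFAULT_CONTROL_ROW: tuple[Role, ...] = (
    Role.WT_LYSATE,
    Role.BUFFER,
    Role.BSA,
    Role.POLY_LYSINE,
    Role.PROTEIN_A,
    Role.ANTIHUMAN,
    Role.LANDMARK,
)

GPR_COLUMNS = ("Block", "Row", "Column", "Name", "F635 Median", "B635 Median", "Flags")

SPOT_FRAME_COLUMNS = ("block", "row", "column", "name", "role", "foreground", "background", "flag")


@dataclass(frozen=True)
class SpotRecord:
    """One printed spot: grid position, identity, role and raw fluorescence.

    ``flag`` follows GenePix convention: 0 is a good spot, negative values
    exclude the spot from all downstream aggregation.
    """

    block: int
    row: int
    column: int
    name: str
    role: Role
    foreground: float
    background: float
    flag: int = 0

    def __post_init__(self) -> None:
        if min(self.block, self.row, self.column) < 1:
            raise IntegrityError(
                f"grid coordinates must be >= 1, got {(self.block, self.row, self.column)}"
            )
        if self.foreground < 0 or self.background < 0:
            raise IntegrityError("foreground and background medians must be >= 0")
        if not isinstance(self.role, Role):
            object.__setattr__(self, "role", Role(self.role))


def _validate_spot_frame(spots: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SPOT_FRAME_COLUMNS if c not in spots.columns]
    if missing:
        raise FormatError(f"spot frame missing required column(s): {', '.join(missing)}")
    spots = spots.loc[:, list(SPOT_FRAME_COLUMNS)].reset_index(drop=True)
    for col in ("block", "row", "column"):
        spots[col] = spots[col].astype(int)
        if (spots[col] < 1).any():
            raise IntegrityError(f"column {col!r} must be >= 1 (1-based grid)")
    spots["flag"] = spots["flag"].astype(int)
    for col in ("foreground", "background"):
        spots[col] = spots[col].astype(float)
        if (spots[col] < 0).any():
            raise IntegrityError(f"column {col!r} contains negative medians")
    spots["name"] = spots["name"].astype(str)
    spots["role"] = spots["role"].map(lambda r: Role(r))
    dup = spots.duplicated(subset=["block", "row", "column"])
    if dup.any():
        first = spots.loc[dup, ["block", "row", "column"]].iloc[0]
        raise IntegrityError(
            f"duplicate grid position (block={first.block}, row={first.row}, "
            f"column={first.column})"
        )
    return spots


@dataclass
class ArrayScan:
    """All spots of one slide scanned in one assay condition.

    ``spots`` is a DataFrame with columns
    ``block, row, column, name, role, foreground, background, flag``
    (one row per spot, positions unique). Construction validates the frame.
    """

    spots: pd.DataFrame
    assay_id: str = ""
    antibody: str = "none"
    condition: str = "experiment"
    batch: str = ""

    def __post_init__(self) -> None:
        if self.antibody not in ANTIBODIES:
            raise IntegrityError(f"unknown antibody {self.antibody!r}; expected one of {ANTIBODIES}")
        if self.condition not in CONDITIONS:
            raise IntegrityError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        self.spots = _validate_spot_frame(self.spots)

    def __len__(self) -> int:
        return len(self.spots)

    @classmethod
    def from_records(
        cls,
        records: Iterable[SpotRecord],
        *,
        assay_id: str = "",
        antibody: str = "none",
        condition: str = "experiment",
        batch: str = "",
    ) -> "ArrayScan":
        rows = [
            (r.block, r.row, r.column, r.name, r.role, r.foreground, r.background, r.flag)
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(SPOT_FRAME_COLUMNS))
        return cls(frame, assay_id=assay_id, antibody=antibody, condition=condition, batch=batch)

    def records(self) -> list[SpotRecord]:
        return [
            SpotRecord(
                int(t.block), int(t.row), int(t.column), t.name, t.role,
                float(t.foreground), float(t.background), int(t.flag),
            )
            for t in self.spots.itertuples(index=False)
        ]

    def grid_signature(self) -> frozenset:
        """The set of occupied grid positions; scans compared together must agree."""
        return frozenset(
            zip(self.spots["block"], self.spots["row"], self.spots["column"])
        )


@dataclass(frozen=True)
class ArrayLayout:
    """Print design: position -> (name, role), plus duplicate groups per clone.

    Invariants enforced on construction: every clone has exactly two spot
    positions (duplicate printing) and clone position sets are disjoint.
    """

    positions: Mapping[tuple[int, int, int], tuple[str, Role]]
    replicate_groups: Mapping[str, tuple[tuple[int, int, int], ...]]
    n_blocks: int = 0
    block_columns: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for clone, group in self.replicate_groups.items():
            if len(group) != 2:
                raise IntegrityError(
                    f"clone {clone!r} has {len(group)} positions; duplicate printing requires 2"
                )
            for pos in group:
                if pos in seen:
                    raise IntegrityError(f"position {pos} assigned to more than one clone")
                seen.add(pos)
                if pos not in self.positions:
                    raise IntegrityError(f"clone {clone!r} position {pos} missing from layout")

    @property
    def clones(self) -> list[str]:
        return list(self.replicate_groups)

    def positions_for_role(self, role: Role) -> list[tuple[int, int, int]]:
        return [pos for pos, (_, r) in self.positions.items() if r is role]

    def grid_signature(self) -> frozenset:
        return frozenset(self.positions)


# ---------------------------------------------------------------------------
# GPR-dialect IO
# ---------------------------------------------------------------------------

_REQUIRED_GPR = {"Block", "Row", "Column", "Name", "F635 Median", "B635 Median", "Flags"}


def _format_au(value: float) -> str:
    """Render an AU value losslessly: integers without a decimal point."""
    f = float(value)
    if f.is_integer():
        return str(int(f))
    return repr(f)


def read_gpr(path, control_vocabulary: Mapping[str, Role] | None = None) -> ArrayScan:
    """Read a GPR/ATF-dialect spot table into an :class:`ArrayScan`.

    Control roles are resolved by exact spot-name match against
    ``control_vocabulary`` (default: the seven control types plus ``WT``);
    unknown names default to ``Role.LYSATE``.

    Raises
    ------
    FormatError
        If the file is not in the dialect or a required column is absent.
    IntegrityError
        If a grid position occurs twice.
    """
    vocab = DEFAULT_CONTROL_VOCABULARY if control_vocabulary is None else control_vocabulary
    with open(path, "r", encoding="utf-8") as fh:
        magic = fh.readline().rstrip("\n")
        if not magic.startswith("ATF"):
            raise FormatError(f"{path}: not an ATF file (first line {magic!r})")
        counts = fh.readline().split("\t")
        try:
            n_header = int(counts[0])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: malformed ATF header-count line") from exc
        meta: dict[str, str] = {}
        for _ in range(n_header):
            line = fh.readline().strip().strip('"')
            if "=" in line:
                key, _, value = line.partition("=")
                meta[key] = value
        body = fh.read()

    try:
        table = pd.read_csv(io.StringIO(body), sep="\t", quotechar='"', dtype={"Name": str})
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed spot table ({exc})") from exc
    missing = sorted(_REQUIRED_GPR - set(table.columns))
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    names = table["Name"].astype(str)
    roles = names.map(lambda n: vocab.get(n, Role.LYSATE))
    spots = pd.DataFrame(
        {
            "block": table["Block"],
            "row": table["Row"],
            "column": table["Column"],
            "name": names,
            "role": roles,
            "foreground": table["F635 Median"],
            "background": table["B635 Median"],
            "flag": table["Flags"],
        }
    )
    return ArrayScan(
        spots,
        assay_id=meta.get("AssayID", os.path.splitext(os.path.basename(str(path)))[0]),
        antibody=meta.get("Antibody", "none"),
        condition=meta.get("Condition", "experiment"),
        batch=meta.get("Batch", ""),
    )


def write_gpr(scan: ArrayScan, path) -> None:
    """Write ``scan`` as a GPR-dialect text file re-readable by :func:`read_gpr`.

    Integer fields round-trip bit-exactly; AU fields round-trip to full
    printed precision (``repr`` of the float).
    """
    if len(scan) == 0:
        raise FormatError("refusing to write an empty scan")
    n_blocks = int(scan.spots["block"].max())
    header = [
        "Type=EclaScreen GPR dialect 1.0",
        f"AssayID={scan.assay_id}",
        f"Antibody={scan.antibody}",
        f"Condition={scan.condition}",
        f"Batch={scan.batch}",
        f"BlockCount={n_blocks}",
    ]
    lines = ["ATF\t1.0", f"{len(header)}\t{len(GPR_COLUMNS)}"]
    lines += [f'"{h}"' for h in header]
    lines.append("\t".join(f'"{c}"' for c in GPR_COLUMNS))
    spots = scan.spots.sort_values(["block", "row", "column"], kind="mergesort")
    for t in spots.itertuples(index=False):
        lines.append(
            "\t".join(
                (
                    str(int(t.block)),
                    str(int(t.row)),
                    str(int(t.column)),
                    f'"{t.name}"',
                    _format_au(t.foreground),
                    _format_au(t.background),
                    str(int(t.flag)),
                )
            )
        )
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# Layout construction
# ---------------------------------------------------------------------------

def read_manifest(path) -> list[str]:
    """Read a plate manifest TSV (plate, well, clone_name) into an ordered clone list.

    Clones are ordered by (plate, well); names must be unique.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"plate", "well", "clone_name"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise FormatError(f"manifest missing required column(s): {', '.join(missing)}")
    table = table.sort_values(["plate", "well"], kind="mergesort")
    names = table["clone_name"].tolist()
    if len(set(names)) != len(names):
        raise IntegrityError("manifest clone names are not unique")
    return names


def build_layout(
    clones: Sequence[str],
    *,
    n_blocks: int = 48,
    block_columns: int = 20,
    control_roles: Sequence[Role] = DEFAULT_CONTROL_ROW,
    max_rows_per_block: int | None = None,
) -> ArrayLayout:
    """Assign each clone two duplicate spots and one control row per block.

    Duplicates are printed side by side in the same row; lysate rows fill
    block 1 first, then block 2, and so on.  The control row (one per block,
    following ``control_roles`` left to right) sits below the last lysate
    row of the fullest block, i.e. at the bottom of each block.  The result
    is a pure function of the inputs.

    Raises
    ------
    CapacityError
        If ``max_rows_per_block`` is given and the clones do not fit; the
        message states the number of blocks that would be required.
    """
    if n_blocks < 1:
        raise CapacityError("n_blocks must be >= 1")
    if len(control_roles) > block_columns:
        raise CapacityError(
            f"control row of {len(control_roles)} roles does not fit in "
            f"{block_columns} columns"
        )
    names = [str(c) for c in clones]
    if len(set(names)) != len(names):
        raise IntegrityError("clone names must be unique")
    pairs_per_row = block_columns // 2
    if pairs_per_row < 1:
        raise CapacityError("block_columns must be >= 2 to hold duplicate pairs")

    n = len(names)
    lysate_rows = math.ceil(n / (pairs_per_row * n_blocks)) if n else 0
    if max_rows_per_block is not None and lysate_rows + 1 > max_rows_per_block:
        need = math.ceil(n / (pairs_per_row * (max_rows_per_block - 1)))
        raise CapacityError(
            f"{n} clones need {need} blocks at {max_rows_per_block} rows/block "
            f"({n_blocks} available)"
        )

    positions: dict[tuple[int, int, int], tuple[str, Role]] = {}
    groups: dict[str, tuple[tuple[int, int, int], ...]] = {}
    pairs_per_block = pairs_per_row * lysate_rows
    for idx, name in enumerate(names):
        block = idx // pairs_per_block + 1
        within = idx % pairs_per_block
        row = within // pairs_per_row + 1
        pair = within % pairs_per_row
        left = (block, row, 2 * pair + 1)
        right = (block, row, 2 * pair + 2)
        positions[left] = (name, Role.LYSATE)
        positions[right] = (name, Role.LYSATE)
        groups[name] = (left, right)

    control_row = lysate_rows + 1
    for block in range(1, n_blocks + 1):
        for col, role in enumerate(control_roles, start=1):
            role = Role(role)
            positions[(block, control_row, col)] = (ROLE_DEFAULT_NAMES[role], role)

    return ArrayLayout(
        positions=positions,
        replicate_groups=groups,
        n_blocks=n_blocks,
        block_columns=block_columns,
    )


def layout_from_scan(scan: ArrayScan) -> ArrayLayout:
    """Reconstruct a layout from a scan's names and roles.

    Lysate-role spots are grouped by name into duplicate pairs; every clone
    must occur exactly twice or the scan is not a duplicate-printed array.
    """
    positions: dict[tuple[int, int, int], tuple[str, Role]] = {}
    groups: dict[str, list[tuple[int, int, int]]] = {}
    for t in scan.spots.itertuples(index=False):
        pos = (int(t.block), int(t.row), int(t.column))
        positions[pos] = (t.name, t.role)
        if t.role is Role.LYSATE:
            groups.setdefault(t.name, []).append(pos)
    return ArrayLayout(
        positions=positions,
        replicate_groups={k: tuple(sorted(v)) for k, v in sorted(groups.items())},
        n_blocks=int(scan.spots["block"].max()),
        block_columns=int(scan.spots["column"].max()),
    )
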