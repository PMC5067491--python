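"""Barcoded microarray model: whitelist, layout geometry and barcode matching.

The array is a rectangular grid of printed oligonucleotide spots at a fixed
centre-to-centre pitch.  Each interior spot carries a unique 18 nt DNA barcode
("spot ID") followed by a 9 nt semi-randomized UMI (pattern ``WSNNWSNNV``) and
an oligo-dT capture sequence; the perimeter is an unbarcoded frame used for
image orientation.  This module holds the static description of that array
(:class:`BarcodeWhitelist`, :class:`ArrayLayout`, :class:`UmiPattern`) and the
barcode-decoding primitives used by the demultiplexer: a pigeonhole k-mer
index for candidate retrieval and exact Hamming matching with a configurable
mismatch budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
BARCODE_LENGTH = 18
FRAME = "FRAME"
UNASSIGNED = "UNASSIGNED"

#: base -> integer code; N gets its own code and mismatches every base (and N)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class MalformedReadError(ValueError):
    """Raised when a read segment has the wrong length or alphabet."""


class ConfigurationError(ValueError):
    """Raised for invalid decoder/layout configuration."""


class WhitelistGenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the distance constraint."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string over {A,C,G,T,N} as a uint8 vector."""
    try:
        return np.fromiter((_CODE[b] for b in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - defensive
        raise MalformedReadError(f"invalid base {exc} in {seq!r}") from exc


def hamming(a: str, b: str) -> int:
    """Hamming distance; N mismatches everything, including another N."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    ea, eb = encode_sequence(a), encode_sequence(b)
    return int(((ea != eb) | (ea == _N_CODE) | (eb == _N_CODE)).sum())


@dataclass(frozen=True)
class UmiPattern:
    """Semi-randomized UMI template in IUPAC code, default ``WSNNWSNNV``.

    W = A/T, S = C/G, N = any base, V = A/C/G.  A UMI is valid iff every
    position's base lies in that position's allowed set; N in a read is never
    valid.
    """

    code: str = "WSNNWSNNV"

    @property
    def length(self) -> int:
        return len(self.code)

    def allowed_sets(self) -> list[str]:
        return [IUPAC[c] for c in self.code]

    def space_size(self) -> int:
        """Number of distinct valid UMIs (product of per-position set sizes)."""
        size = 1
        for c in self.code:
            size *= len(IUPAC[c])
        return size

    def is_valid(self, umi: str) -> bool:
        if len(umi) != self.length:
            raise MalformedReadError(
                f"UMI length {len(umi)} != pattern length {self.length}"
            )
        return all(b in allowed for b, allowed in zip(umi, self.allowed_sets()))

    def sample(self, rng: np.random.Generator, n: int) -> list[str]:
        """Draw n UMIs uniformly over the valid pattern space."""
        cols = []
        for allowed in self.allowed_sets():
            idx = rng.integers(0, len(allowed), size=n)
            cols.append(np.array(list(allowed))[idx])
        return ["".join(row) for row in zip(*cols)]


def umi_is_valid(umi: str, pattern: UmiPattern | None = None) -> bool:
    """True iff ``umi`` fits the semi-randomized template (default WSNNWSNNV)."""
    return (pattern or UmiPattern()).is_valid(umi)


def _min_pairwise_distance(encoded: np.ndarray) -> int:
    """Exact minimum pairwise Hamming distance, vectorised brute force."""
    n = encoded.shape[0]
    if n < 2:
        return encoded.shape[1]
    best = encoded.shape[1]
    # row-vs-all in chunks keeps memory modest for ~1,000 x 18 whitelists
    for i in range(n - 1):
        d = (encoded[i + 1:] != encoded[i]).sum(axis=1).min()
        if d < best:
            best = int(d)
            if best == 0:
                return 0
    return best


@dataclass
class BarcodeWhitelist:
    """The set of printed spot barcodes with their verified separation.

    ``min_pairwise_distance`` is the *true* minimum pairwise Hamming distance,
    recomputed at construction; decoding with up to ``k`` mismatches is
    provably unambiguous whenever it is at least ``2k + 1``.
    """

    ids: list[str]
    sequences: list[str]
    min_pairwise_distance: int = field(init=False)
    _encoded: np.ndarray = field(init=False, repr=False)
    _row_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must align")
        lengths = {len(s) for s in self.sequences}
        if lengths and lengths != {BARCODE_LENGTH}:
            raise ValueError(f"all barcodes must be {BARCODE_LENGTH} nt")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("barcode sequences must be distinct")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("barcode ids must be distinct")
        self._encoded = (
            np.stack([encode_sequence(s) for s in self.sequences])
            if self.sequences
            else np.zeros((0, BARCODE_LENGTH), dtype=np.uint8)
        )
        self._row_of = {b: i for i, b in enumerate(self.ids)}
        self.min_pairwise_distance = _min_pairwise_distance(self._encoded)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return BARCODE_LENGTH

    @property
    def encoded(self) -> np.ndarray:
        return self._encoded

    def sequence_of(self, barcode_id: str) -> str:
        return self.sequences[self._row_of[barcode_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"barcode_id": self.ids, "sequence": self.sequences})


def generate_whitelist(
    n: int,
    min_distance: int = 5,
    seed: int | np.random.Generator = 0,
    max_tries: int = 2_000_000,
) -> BarcodeWhitelist:
    """Sample ``n`` 18 nt barcodes with pairwise Hamming distance >= min_distance.

    Rejection sampling against the accepted set; deterministic under a fixed
    seed.  Raises :class:`WhitelistGenerationError` when the retry budget is
    exhausted (the constraint is then presumed unsatisfiable at this length).
    """
    if not 0 <= min_distance <= BARCODE_LENGTH:
        raise ConfigurationError("min_distance must be in [0, 18]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accepted = np.empty((n, BARCODE_LENGTH), dtype=np.uint8)
    count = 0
    tries = 0
    while count < n:
        if tries >= max_tries:
            raise WhitelistGenerationError(
                f"accepted only {count}/{n} barcodes after {max_tries} tries"
            )
        cand = rng.integers(0, 4, size=BARCODE_LENGTH, dtype=np.uint8)
        tries += 1
        if count and (accepted[:count] != cand).sum(axis=1).min() < min_distance:
            continue
        accepted[count] = cand
        count += 1
    seqs = ["".join(BASES[c] for c in row) for row in accepted]
    ids = [f"BC{i + 1:04d}" for i in range(n)]
    return BarcodeWhitelist(ids=ids, sequences=seqs)


@dataclass
class ArrayLayout:
    """Spot grid: row/col indices, physical micrometre coordinates, barcodes.

    Coordinates are 0-based row-major with the origin at the centre of spot
    (0, 0): ``x_um = col * pitch_um`` and ``y_um = row * pitch_um``.  Frame
    spots carry the :data:`FRAME` marker instead of a barcode.
    """

    n_rows: int
    n_cols: int
    pitch_um: float
    spots: pd.DataFrame  # spot_id, row, col, x_um, y_um, barcode_id, is_frame

    def __post_init__(self) -> None:
        s = self.spots
        if not np.allclose(s["x_um"], s["col"] * self.pitch_um) or not np.allclose(
            s["y_um"], s["row"] * self.pitch_um
        ):
            raise ValueError("coordinates inconsistent with pitch/grid")
        used = s.loc[~s["is_frame"], "barcode_id"]
        if used.duplicated().any():
            raise ValueError("each barcode_id may be used at most once")

    @property
    def barcode_spots(self) -> pd.DataFrame:
        return self.spots.loc[~self.spots["is_frame"]].reset_index(drop=True)

    @property
    def barcode_ids(self) -> list[str]:
        return list(self.barcode_spots["barcode_id"])

    def spot_centres(self) -> np.ndarray:
        return self.spots[["x_um", "y_um"]].to_numpy(dtype=float)


def default_layout(
    whitelist: BarcodeWhitelist,
    n_rows: int = 33,
    n_cols: int = 35,
    pitch_um: float = 200.0,
    reserve_corners: bool = True,
) -> ArrayLayout:
    """Build the standard layout: perimeter frame plus corner-reserved spots.

    On the default 33 x 35 grid the full perimeter (132 spots) and the four
    2 x 2 interior blocks adjacent to the corners (16 spots) are frame
    markers, leaving exactly 1,007 positions for unique barcodes.  Smaller
    grids for simulation can disable the corner reservation.
    """
    reserved: set[tuple[int, int]] = set()
    if reserve_corners:
        if n_rows < 7 or n_cols < 7:
            raise ConfigurationError("grid too small for corner reservation")
        for r0 in (1, n_rows - 3):
            for c0 in (1, n_cols - 3):
                for dr in (0, 1):
                    for dc in (0, 1):
                        reserved.add((r0 + dr, c0 + dc))
    interior = [
        (r, c)
        for r in range(1, n_rows - 1)
        for c in range(1, n_cols - 1)
        if (r, c) not in reserved
    ]
    if len(whitelist) < len(interior):
        raise ConfigurationError(
            f"layout needs {len(interior)} barcodes, whitelist has {len(whitelist)}"
        )
    assign = iter(whitelist.ids)
    interior_set = set(interior)
    rows = []
    for r in range(n_rows):
        for c in range(n_cols):
            idx = r * n_cols + c
            is_interior = (r, c) in interior_set
            rows.append(
                {
                    "spot_id": f"spot{idx:04d}",
                    "row": r,
                    "col": c,
                    "x_um": c * pitch_um,
                    "y_um": r * pitch_um,
                    "barcode_id": next(assign) if is_interior else FRAME,
                    "is_frame": not is_interior,
                }
            )
    return ArrayLayout(n_rows=n_rows, n_cols=n_cols, pitch_um=pitch_um,
                       spots=pd.DataFrame(rows))


def write_layout_tsv(path, layout: ArrayLayout, whitelist: BarcodeWhitelist) -> None:
    """Write the layout + barcode sequences as the standard 6-column TSV."""
    df = layout.spots.copy()
    seq_of = dict(zip(whitelist.ids, whitelist.sequences))
    df["sequence"] = [seq_of.get(b, "") for b in df["barcode_id"]]
    df["is_frame"] = df["is_frame"].astype(int)
    df[["spot_id", "row", "col", "barcode_id", "sequence", "is_frame"]].to_csv(
        path, sep="\t", index=False
    )


def read_layout_tsv(path, pitch_um: float = 200.0) -> tuple[ArrayLayout, BarcodeWhitelist]:
    """Read a layout TSV (spot_id, row, col, barcode_id, sequence, is_frame)."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode_id": str, "sequence": str})
    required = {"spot_id", "row", "col", "barcode_id", "sequence", "is_frame"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"layout TSV missing columns {required - set(df.columns)}")
    df["is_frame"] = df["is_frame"].astype(bool)
    df["x_um"] = df["col"] * pitch_um
    df["y_um"] = df["row"] * pitch_um
    non_frame = df.loc[~df["is_frame"]]
    whitelist = BarcodeWhitelist(
        ids=list(non_frame["barcode_id"]), sequences=list(non_frame["sequence"])
    )
    layout = ArrayLayout(
        n_rows=int(df["row"].max()) + 1,
        n_cols=int(df["col"].max()) + 1,
        pitch_um=pitch_um,
        spots=df[["spot_id", "row", "col", "x_um", "y_um", "barcode_id", "is_frame"]],
    )
    return layout, whitelist


# ---------------------------------------------------------------------------
# k-mer candidate index and Hamming matching


def build_kmer_index(
    whitelist: BarcodeWhitelist, segment_length: int = 6
) -> dict[tuple[int, str], list[int]]:
    """Index whitelist barcodes by disjoint segments for candidate retrieval.

    The barcode is cut into ``18 / segment_length`` disjoint segments; a read
    within ``k`` substitutions of a whitelist barcode has at least one segment
    exactly equal to the barcode's (pigeonhole) whenever the number of
    segments exceeds ``k``.  Keys are ``(offset, segment)``; values are row
    indices into the whitelist.
    """
    if BARCODE_LENGTH % segment_length != 0:
        raise ConfigurationError(
            f"segment_length {segment_length} does not divide {BARCODE_LENGTH}"
        )
    index: dict[tuple[int, str], list[int]] = {}
    for row, seq in enumerate(whitelist.sequences):
        for offset in range(0, BARCODE_LENGTH, segment_length):
            key = (offset, seq[offset : offset + segment_length])
            index.setdefault(key, []).append(row)
    return index


def _resolve(
    dists: np.ndarray, rows: np.ndarray, whitelist: BarcodeWhitelist, max_mismatches: int
) -> tuple[str, int] | None:
    """Pick the unique best hit within budget; ties -> None (UNASSIGNED)."""
    if dists.size == 0:
        return None
    order = np.argsort(dists, kind="stable")
    best = int(dists[order[0]])
    if best > max_mismatches:
        return None
    if order.size > 1 and int(dists[order[1]]) == best:
        return None
    return whitelist.ids[int(rows[order[0]])], best


def match_barcode(
    observed: str,
    whitelist: BarcodeWhitelist,
    index: dict[tuple[int, str], list[int]] | None = None,
    max_mismatches: int = 2,
    segment_length: int = 6,
) -> tuple[str, int] | None:
    """Decode an observed 18-mer against the whitelist via the k-mer index.

    Returns ``(barcode_id, distance)`` for the unique whitelist entry within
    ``max_mismatches`` substitutions (strictly closer than any other entry),
    or ``None`` when no entry qualifies or the minimum is tied.  N bases count
    as mismatches to every base.
    """
    if len(observed) != BARCODE_LENGTH:
        raise MalformedReadError(f"barcode length {len(observed)} != {BARCODE_LENGTH}")
    if BARCODE_LENGTH // segment_length < max_mismatches + 1:
        raise ConfigurationError(
            "need at least max_mismatches + 1 segments for pigeonhole recall"
        )
    if index is None:
        index = build_kmer_index(whitelist, segment_length)
    candidates: set[int] = set()
    for offset in range(0, BARCODE_LENGTH, segment_length):
        candidates.update(
            index.get((offset, observed[offset : offset + segment_length]), ())
        )
    if not candidates:
        return None
    rows = np.fromiter(candidates, dtype=np.intp, count=len(candidates))
    enc = encode_sequence(observed)
    sub = whitelist.encoded[rows]
    dists = ((sub != enc) | (enc == _N_CODE)).sum(axis=1)
    return _resolve(dists, rows, whitelist, max_mismatches)


def exhaustive_match(
    observed: str, whitelist: BarcodeWhitelist, max_mismatches: int = 2
) -> tuple[str, int] | None:
    """Full-scan Hamming decoder with the same contract as :func:`match_barcode`.

    Used as the independent reference the k-mer path is checked against.
    """
    if len(observed) != BARCODE_LENGTH:
        raise MalformedReadError(f"barcode length {len(observed)} != {BARCODE_LENGTH}")
    enc = encode_sequence(observed)
    dists = ((whitelist.encoded != enc) | (enc == _N_CODE)).sum(axis=1)
    rows = np.arange(len(whitelist), dtype=np.intp)
    return _resolve(dists, rows, whitelist, max_mismatches)


def substitution_neighbours(seq: str, n_subs: int):
    """Yield every sequence at Hamming distance exactly ``n_subs`` from seq."""
    for positions in itertools.combinations(range(len(seq)), n_subs):
        choices = [[b for b in BASES if b != seq[p]] for p in positions]
        for repl in itertools.product(*choices):
            out = list(seq)
            for p, b in zip(positions, repl):
                out[p] = b
            yield "".join(out)
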