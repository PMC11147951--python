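"""DNA-shape profiles from nucleotide sequence via a pentamer lookup table.

Each 5-mer of a sequence predicts four structural parameters of the central
base pair / the two base-pair steps flanking it:

* **MGW** — minor groove width (Å), one value per pentamer center.
* **ProT** — propeller twist (degrees), one value per pentamer center.
* **HelT** — helix twist (degrees), two values per pentamer: one for each of
  the two base-pair steps flanking the center.
* **Roll** — roll angle (degrees), likewise two per pentamer.

A :class:`ShapeProfile` aligns these predictions to sequence positions.
Single-position features (MGW, ProT) are defined wherever a full pentamer is
centered, i.e. at 1-based positions ``3 .. L-2``.  Step features (HelT, Roll)
are first averaged per base-pair step over every pentamer predicting that
step, then assigned to positions as the mean of the (defined) steps flanking
each position; this leaves the first and last position undefined, giving
``L-2`` defined values.  For a 147-bp sequence the per-feature defined counts
are therefore 143, 143, 145 and 145 — 576 values in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FEATURES = ("MGW", "ProT", "HelT", "Roll")

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_POW4 = 4 ** np.arange(4, -1, -1)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as integers A=0, C=1, G=2, T=3; -1 for anything else."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pentamer_code(pentamer: str) -> int:
    codes = encode_sequence(pentamer)
    if len(codes) != 5 or (codes < 0).any():
        raise ValueError(f"not a valid ACGT pentamer: {pentamer!r}")
    return int(codes @ _POW4)


def code_to_pentamer(code: int) -> str:
    bases = "ACGT"
    return "".join(bases[(code >> (2 * (4 - i))) & 3] for i in range(5))


def _rc_code(code: int) -> int:
    """Pentamer code of the reverse complement, computed on the 2-bit encoding."""
    out = 0
    for _ in range(5):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


RC_CODES = np.array([_rc_code(c) for c in range(1024)], dtype=np.int64)


class PentamerTableError(ValueError):
    pass


@dataclass
class PentamerTable:
    """5-mer -> shape-value lookup grounding all featurization.

    Values are stored densely, indexed by the base-4 pentamer code; ``present``
    marks which of the 1024 possible pentamers the table defines.  ``helt`` and
    ``roll`` hold two columns: the step before and the step after the pentamer
    center, in that order.
    """

    mgw: np.ndarray
    prot: np.ndarray
    helt: np.ndarray
    roll: np.ndarray
    present: np.ndarray
    source: str = ""
    rc_symmetric: bool = False
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.present.sum())

    def __contains__(self, pentamer: str) -> bool:
        return bool(self.present[pentamer_code(pentamer)])

    @property
    def complete(self) -> bool:
        return len(self) == 1024

    def lookup(self, pentamer: str) -> dict:
        c = pentamer_code(pentamer)
        if not self.present[c]:
            raise KeyError(f"pentamer not in table: {pentamer}")
        return {
            "mgw": float(self.mgw[c]),
            "prot": float(self.prot[c]),
            "helt": (float(self.helt[c, 0]), float(self.helt[c, 1])),
            "roll": (float(self.roll[c, 0]), float(self.roll[c, 1])),
        }

    def missing_pentamers(self) -> list[str]:
        return [code_to_pentamer(int(c)) for c in np.flatnonzero(~self.present)]

    def check_rc_symmetric(self, atol: float = 1e-9) -> bool:
        """True when every pentamer and its reverse complement agree.

        MGW and ProT must be equal between a pentamer and its reverse
        complement; the HelT and Roll step pairs must swap order (the step
        before the center maps to the step after it on the other strand).
        """
        rc = RC_CODES
        if not np.array_equal(self.present, self.present[rc]):
            return False
        ok = np.allclose(self.mgw[self.present], self.mgw[rc][self.present], atol=atol)
        ok &= np.allclose(self.prot[self.present], self.prot[rc][self.present], atol=atol)
        ok &= np.allclose(self.helt[self.present], self.helt[rc][self.present][:, ::-1], atol=atol)
        ok &= np.allclose(self.roll[self.present], self.roll[rc][self.present][:, ::-1], atol=atol)
        return bool(ok)

    @classmethod
    def from_entries(cls, entries: dict, source: str = "", rc_symmetric: bool = False,
                     metadata: dict | None = None) -> "PentamerTable":
        """Build a table from ``{pentamer: (mgw, prot, helt1, helt2, roll1, roll2)}``."""
        mgw = np.full(1024, np.nan)
        prot = np.full(1024, np.nan)
        helt = np.full((1024, 2), np.nan)
        roll = np.full((1024, 2), np.nan)
        present = np.zeros(1024, dtype=bool)
        for pent, vals in entries.items():
            c = pentamer_code(pent)
            if present[c]:
                raise PentamerTableError(f"duplicate pentamer: {pent}")
            mgw[c], prot[c], helt[c, 0], helt[c, 1], roll[c, 0], roll[c, 1] = vals
            present[c] = True
        return cls(mgw, prot, helt, roll, present, source=source,
                   rc_symmetric=rc_symmetric, metadata=metadata or {})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.source:
                fh.write(f"##source={self.source}\n")
            fh.write(f"##rc_symmetric={'true' if self.rc_symmetric else 'false'}\n")
            for key, val in self.metadata.items():
                fh.write(f"##{key}={val}\n")
            fh.write("pentamer\tMGW\tProT\tHelT1\tHelT2\tRoll1\tRoll2\n")
            for c in np.flatnonzero(self.present):
                fh.write(
                    f"{code_to_pentamer(int(c))}\t{self.mgw[c]:.6g}\t{self.prot[c]:.6g}"
                    f"\t{self.helt[c, 0]:.6g}\t{self.helt[c, 1]:.6g}"
                    f"\t{self.roll[c, 0]:.6g}\t{self.roll[c, 1]:.6g}\n"
                )


def load_pentamer_table(path, strict: bool = False) -> PentamerTable:
    """Parse a pentamer shape table from TSV.

    The dialect: an optional block of ``##key=value`` metadata comments,
    ``#`` comment lines, a header line starting with ``pentamer``, then one
    row per 5-mer with columns ``pentamer MGW ProT HelT1 HelT2 Roll1 Roll2``.
    With ``strict`` the table must define all 1024 pentamers.
    """
    entries: dict[str, tuple] = {}
    meta: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##"):
                if "=" in line:
                    key, _, val = line[2:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "pentamer":
                continue
            if len(fields) != 7:
                raise PentamerTableError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            pent = fields[0].upper()
            try:
                code = pentamer_code(pent)
            except ValueError:
                raise PentamerTableError(
                    f"{path}:{lineno}: invalid pentamer key {fields[0]!r}"
                ) from None
            if pent in entries:
                raise PentamerTableError(f"{path}:{lineno}: duplicate pentamer {pent}")
            try:
                vals = tuple(float(x) for x in fields[1:])
            except ValueError:
                raise PentamerTableError(
                    f"{path}:{lineno}: non-numeric shape value"
                ) from None
            entries[pent] = vals
            del code
    rc_flag = meta.pop("rc_symmetric", "false").lower() in ("true", "1", "yes")
    table = PentamerTable.from_entries(
        entries, source=meta.pop("source", ""), rc_symmetric=rc_flag, metadata=meta
    )
    if strict and not table.complete:
        missing = table.missing_pentamers()
        shown = ", ".join(missing[:5]) + ("..." if len(missing) > 5 else "")
        raise PentamerTableError(
            f"{path}: table incomplete, {len(missing)} pentamers missing: {shown}"
        )
    return table


@dataclass
class ShapeProfile:
    """Per-position MGW/ProT/HelT/Roll series for one sequence.

    Arrays are full sequence length with NaN at undefined (edge) positions;
    positions are 0-based indices into the sequence here, with the 1-based
    convention of the defined ranges documented at module level.
    """

    seq_length: int
    mgw: np.ndarray
    prot: np.ndarray
    helt: np.ndarray
    roll: np.ndarray

    def values(self, feature: str) -> np.ndarray:
        return getattr(self, feature.lower())

    def mask(self, feature: str) -> np.ndarray:
        """Boolean mask of defined positions for a feature."""
        return ~np.isnan(self.values(feature))

    def defined(self, feature: str) -> np.ndarray:
        """The defined values of a feature in positional order."""
        v = self.values(feature)
        return v[~np.isnan(v)]

    def defined_counts(self) -> dict:
        return {f: int(self.mask(f).sum()) for f in FEATURES}


def _pentamer_codes(codes: np.ndarray) -> np.ndarray:
    """Code of the pentamer centered at each position (NaN-free: -1 where undefined)."""
    n = codes.size
    out = np.full(n, -1, dtype=np.int64)
    if n < 5:
        return out
    window = (
        codes[:-4] * 256 + codes[1:-3] * 64 + codes[2:-2] * 16
        + codes[3:-1] * 4 + codes[4:]
    )
    valid = (
        (codes[:-4] >= 0) & (codes[1:-3] >= 0) & (codes[2:-2] >= 0)
        & (codes[3:-1] >= 0) & (codes[4:] >= 0)
    )
    out[2:n - 2] = np.where(valid, window, -1)
    return out


def step_contributions(codes: np.ndarray, table: PentamerTable):
    """Per-step HelT/Roll contributions from flanking pentamers.

    Returns ``(h_before, h_after, r_before, r_after)`` where for the base-pair
    step between 0-based positions ``t`` and ``t+1``:

    * ``*_after[t]``  — prediction from the pentamer centered at ``t`` (its
      "step after center" column), defined for centers 2..L-3;
    * ``*_before[t]`` — prediction from the pentamer centered at ``t+1`` (its
      "step before center" column).

    NaN marks undefined entries; the scanner reuses these genome-wide.
    """
    n = codes.size
    pents = _pentamer_codes(codes)
    ok = pents >= 0
    safe = np.where(ok, pents, 0)

    h_after = np.full(n, np.nan)
    r_after = np.full(n, np.nan)
    h_after[ok] = table.helt[safe[ok], 1]
    r_after[ok] = table.roll[safe[ok], 1]

    h_before = np.full(n, np.nan)
    r_before = np.full(n, np.nan)
    shifted_ok = np.zeros(n, dtype=bool)
    shifted_ok[:-1] = ok[1:]
    idx = np.flatnonzero(shifted_ok)
    h_before[idx] = table.helt[safe[idx + 1], 0]
    r_before[idx] = table.roll[safe[idx + 1], 0]
    return h_before, h_after, r_before, r_after


def _steps_to_positions(step_vals: np.ndarray) -> np.ndarray:
    """Mean of the defined base-pair steps flanking each position."""
    n = step_vals.size
    left = np.full(n, np.nan)
    left[1:] = step_vals[:-1]
    right = step_vals  # step t sits to the right of position t
    stacked = np.vstack([left, right])
    cnt = (~np.isnan(stacked)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        pos = np.where(cnt > 0, np.nansum(stacked, axis=0) / np.maximum(cnt, 1), np.nan)
    return pos


def compute_shape(seq: str, table: PentamerTable) -> ShapeProfile:
    """Compute the four DNA-shape series for one ACGT sequence.

    MGW/ProT at a position come from the pentamer centered there.  HelT/Roll
    are predicted per base-pair step (each step averaged over the pentamers
    flanking it) and then assigned per position as the mean of the defined
    flanking steps.  Sequences containing non-ACGT characters are rejected;
    masking is the genome scanner's responsibility.
    """
    if len(seq) < 5:
        raise ValueError(f"sequence too short for pentamer lookup: {len(seq)} < 5")
    codes = encode_sequence(seq)
    if (codes < 0).any():
        bad = seq[int(np.flatnonzero(codes < 0)[0])]
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")

    n = codes.size
    pents = _pentamer_codes(codes)
    used = pents[pents >= 0]
    if not table.present[used].all():
        miss = code_to_pentamer(int(used[~table.present[used]][0]))
        raise KeyError(f"pentamer not in table: {miss}")

    mgw = np.full(n, np.nan)
    prot = np.full(n, np.nan)
    ok = pents >= 0
    mgw[ok] = table.mgw[pents[ok]]
    prot[ok] = table.prot[pents[ok]]

    h_before, h_after, r_before, r_after = step_contributions(codes, table)

    def mean_pair(a, b):
        stacked = np.vstack([a, b])
        cnt = (~np.isnan(stacked)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, np.nansum(stacked, axis=0) / np.maximum(cnt, 1), np.nan)

    helt_steps = mean_pair(h_before, h_after)
    roll_steps = mean_pair(r_before, r_after)

    return ShapeProfile(
        seq_length=n,
        mgw=mgw,
        prot=prot,
        helt=_steps_to_positions(helt_steps),
        roll=_steps_to_positions(roll_steps),
    )
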