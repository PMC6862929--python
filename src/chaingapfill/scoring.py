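"""Alignment scoring: substitution matrix, affine gaps, and stage thresholds.

The default scheme is the standard nucleotide matrix used for cross-species
genome alignment (HOXD70) with affine gap penalties where a gap of length
``g`` costs ``gap_open + g * gap_extend``.  The three stage thresholds
follow seed-and-extend convention:

* ``hsp_threshold`` (K) — minimum score of an ungapped extension (HSP),
* ``gapped_threshold`` (L) — minimum score of a gapped local alignment,
* ``y_drop`` (Y) — gapped extension abandons cells whose score falls more
  than Y below the best score seen.

``h_inner`` (the inner-alignment threshold H of some aligners) is accepted
so existing parameter files parse, but plays no role here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["ScoringScheme", "default_scoring", "encode", "BASES", "N_CODE"]

BASES = "ACGT"
N_CODE = 4  # matrix row/column for N and any other symbol

# byte -> code lookup; everything unknown maps to N_CODE
_ENCODE_TABLE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes A,C,G,T -> 0..3, else 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[raw]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties, and stage thresholds.

    ``matrix`` is a 5x5 int array over (A, C, G, T, N); every entry in the
    N row/column holds the worst substitution score, so columns touching N
    are maximally penalized and can never carry an alignment on their own.
    """

    matrix: np.ndarray
    gap_open: int = 400
    gap_extend: int = 30
    hsp_threshold: int = 2400
    gapped_threshold: int = 3000
    y_drop: int = 9400
    x_drop: int | None = None
    h_inner: int = 2000  # accepted for config compatibility, unused

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.shape == (4, 4):
            m = _with_n(m)
        if m.shape != (5, 5):
            raise ValueError("matrix must be 4x4 over ACGT (or 5x5 with N)")
        if np.any(np.diag(m)[:4] <= 0):
            raise ValueError("diagonal matrix entries must be positive")
        object.__setattr__(self, "matrix", m)
        for name in ("hsp_threshold", "gapped_threshold", "y_drop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @property
    def effective_x_drop(self) -> int:
        """X-drop bound for ungapped extension; default 10x max diagonal."""
        if self.x_drop is not None:
            return self.x_drop
        return 10 * int(np.max(np.diag(self.matrix)[:4]))

    def score_pair(self, a: str, b: str) -> int:
        return int(self.matrix[encode(a)[0], encode(b)[0]])

    def with_thresholds(self, **kwargs) -> "ScoringScheme":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "ScoringScheme":
        """Parse a LASTZ-style score file (O/E assignments plus a matrix)."""
        text = Path(path).read_text()
        return cls._from_text(text, **overrides)

    @classmethod
    def _from_text(cls, text: str, **overrides) -> "ScoringScheme":
        params: dict[str, int] = {}
        rows: list[list[int]] = []
        order: list[str] = []
        header: list[str] | None = None
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, value = (t.strip() for t in line.split("=", 1))
                params[key.upper()] = int(value)
                continue
            tokens = line.split()
            if all(t.upper() in BASES for t in tokens):
                header = [t.upper() for t in tokens]
                continue
            if tokens[0].upper() in BASES:
                order.append(tokens[0].upper())
                rows.append([int(t) for t in tokens[1:]])
        if header is None or len(rows) != 4:
            raise ValueError("score file must contain a 4x4 ACGT matrix")
        m = np.zeros((4, 4), dtype=np.int64)
        for base, row in zip(order, rows):
            for col, value in zip(header, row):
                m[BASES.index(base), BASES.index(col)] = value
        kwargs: dict = {"matrix": m}
        if "O" in params:
            kwargs["gap_open"] = params["O"]
        if "E" in params:
            kwargs["gap_extend"] = params["E"]
        if "K" in params:
            kwargs["hsp_threshold"] = params["K"]
        if "L" in params:
            kwargs["gapped_threshold"] = params["L"]
        if "Y" in params:
            kwargs["y_drop"] = params["Y"]
        if "H" in params:
            kwargs["h_inner"] = params["H"]
        kwargs.update(overrides)
        return cls(**kwargs)


def _with_n(m4: np.ndarray) -> np.ndarray:
    worst = int(m4.min())
    m5 = np.full((5, 5), worst, dtype=np.int64)
    m5[:4, :4] = m4
    return m5


def default_scoring(**overrides) -> ScoringScheme:
    """The packaged default scheme (HOXD70, O=400, E=30, K/L/Y defaults)."""
    ref = resources.files("chaingapfill.data") / "lastz_default.scores"
    return ScoringScheme._from_text(ref.read_text(), **overrides)
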