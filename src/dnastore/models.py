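"""Closed-form storage-overhead models.

Symbols (sizes in bits unless noted):

* ``S_o`` original data size, ``S_c`` compressed size,
  ``r_c = S_c / S_o`` the compression ratio;
* ``S_T`` tool (decompression program) size, ``S_h`` per-file container
  header size;
* ``n`` number of data files sharing one tool,
  ``S_D`` (or per-file ``S_Di``) the data file sizes;
* ``L_s`` maximal fragment length and ``L_p`` primer length, in nt;
* ``a`` the codec's base factor (bases per bit); bare-stream storage
  density is ``d = 1/a`` bits per base.

The *compression efficiency* ``e_c = 1 - (r_c * S_o + S_T) / S_o``
measures the net saving of storing compressed data together with its
tool. Two consequences: with no tool stored (``S_T = 0``) it reduces to
the ideal ``1 - r_c``; and it drops to zero or below once
``S_T >= (1 - r_c) * S_o``, so ``S_T / (1 - r_c)`` is the break-even
original size.

Stored binary size per method::

    Sb_1-1CS = sum(r_c * S_Di) + n * (S_h + S_T)
    Sb_M-1CI = sum(r_c * S_Di) + n * (S_h + 2 L_p) + S_T
    Sb_1-MCI = sum(r_c * S_Di) + n * S_h + S_T

and total bases after fragmenting and adding primers::

    Sd_1-1CS = a * Sb_1-1CS * (1 + 2 L_p / (L_s - 2 L_p))
    Sd_M-1CI = a * Sb_M-1CI * (1 + 2 L_p / (L_s - 2 L_p))
    Sd_1-MCI = a * Sb_1-MCI
               + (sum(r_c * S_Di) + n * S_h) * a / L_s * 2 L_p
               + S_T * a / (L_s - (n+1) L_p) * (n+1) L_p

The Sb/Sd forms use real-valued fragment counts, exactly as the model is
usually written; the emission path in :mod:`dnastore.storage` uses
integer ceilings, and the agreement between the two is a tested property
(within one codec word per stream).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CapacityError
from .storage import METHOD_1_1CS, METHOD_1_MCI, METHOD_M_1CI, METHODS


@dataclass(frozen=True)
class SystemParameters:
    """All model symbols in one place.

    Defaults follow the reference parameter set used for the model
    sweeps: S_h = 10, S_T = 2010, L_p = 20, a = 1/1.6, S_D = 100000,
    r_c = 0.34, L_s = 220.
    """

    n: int = 3
    S_D: float | None = 100_000.0
    S_Di: tuple[float, ...] | None = None
    S_h: float = 10.0
    S_T: float = 2_010.0
    L_s: int = 220
    L_p: int = 20
    a: float = 1 / 1.6
    r_c: float = 0.34

    def sizes(self) -> tuple[float, ...]:
        if self.S_Di is not None:
            if len(self.S_Di) != self.n:
                raise ValueError(
                    f"S_Di has {len(self.S_Di)} entries but n={self.n}")
            return tuple(self.S_Di)
        if self.S_D is None:
            raise ValueError("provide S_D or S_Di")
        return (self.S_D,) * self.n


@dataclass(frozen=True)
class CompressionProfile:
    """Measured compression figures for one file/tool combination."""

    S_o: float
    S_c: float
    S_T: float

    @property
    def r_c(self) -> float:
        return self.S_c / self.S_o

    @property
    def e(self) -> float:
        return (self.r_c * self.S_o + self.S_T) / self.S_o

    @property
    def e_c(self) -> float:
        return 1.0 - self.e


def compression_efficiency(r_c: float, S_o: float, S_T: float) -> float:
    """Net saving e_c = 1 - (r_c * S_o + S_T) / S_o.

    Equals 1 - r_c when S_T = 0 (the ideal case) and is <= 0 once
    S_T >= (1 - r_c) * S_o.
    """
    if S_o <= 0:
        raise ValueError("S_o must be positive")
    if r_c < 0 or S_T < 0:
        raise ValueError("r_c and S_T must be non-negative")
    return 1.0 - (r_c * S_o + S_T) / S_o


def breakeven_S_o(r_c: float, S_T: float) -> float:
    """Minimal original size with non-negative e_c: S_T / (1 - r_c)."""
    if r_c >= 1:
        raise ValueError(
            "no break-even exists when the compression ratio is >= 1")
    return S_T / (1.0 - r_c)


def sb(method: str, params: SystemParameters) -> float:
    """Stored binary size (bits) for one method."""
    compressed = params.r_c * sum(params.sizes())
    if method == METHOD_1_1CS:
        return compressed + params.n * (params.S_h + params.S_T)
    if method == METHOD_M_1CI:
        return (compressed + params.n * (params.S_h + 2 * params.L_p)
                + params.S_T)
    if method == METHOD_1_MCI:
        return compressed + params.n * params.S_h + params.S_T
    raise ValueError(f"unknown storage method {method!r}")


def sd(method: str, params: SystemParameters) -> float:
    """Total base count (nt) after fragmenting and adding primers."""
    if method in (METHOD_1_1CS, METHOD_M_1CI):
        denom = params.L_s - 2 * params.L_p
        if denom <= 0:
            raise CapacityError(
                f"L_s={params.L_s} leaves no payload at L_p={params.L_p}")
        return (params.a * sb(method, params)
                * (1 + 2 * params.L_p / denom))
    if method == METHOD_1_MCI:
        denom = params.L_s - (params.n + 1) * params.L_p
        if denom <= 0:
            raise CapacityError(
                f"a tool fragment shared by n={params.n} files has no "
                f"payload at L_s={params.L_s}, L_p={params.L_p}")
        compressed_plus_headers = (params.r_c * sum(params.sizes())
                                   + params.n * params.S_h)
        return (params.a * sb(METHOD_1_MCI, params)
                + compressed_plus_headers * params.a / params.L_s
                * 2 * params.L_p
                + params.S_T * params.a / denom
                * (params.n + 1) * params.L_p)
    raise ValueError(f"unknown storage method {method!r}")


def storage_density(S_o: float, S_b: float) -> float:
    """Bits represented per stored base, d = S_o / S_b.

    For a bare codec stream (no primers or headers) this equals 1/a."""
    if S_b <= 0:
        raise ValueError("S_b must be positive")
    return S_o / S_b


def sweep(params: SystemParameters,
          vary: Mapping[str, Sequence],
          methods: Iterable[str] = METHODS) -> pd.DataFrame:
    """Evaluate Sb/Sd/e_c/d over the cartesian product of *vary* ranges.

    *vary* maps SystemParameters field names to value sequences, e.g.
    ``{"L_s": range(100, 401, 20)}`` or ``{"n": range(1, 51)}``. Returns
    a deterministic DataFrame with one row per combination, a column per
    varied field, an ``ls_lp_ratio`` column, and ``Sb_<m>`` / ``Sd_<m>``
    columns per method.
    """
    if not vary or any(len(v) == 0 for v in vary.values()):
        raise ValueError("vary must give at least one non-empty range")
    methods = list(methods)
    keys = list(vary)
    rows = []
    for combo in itertools.product(*(vary[k] for k in keys)):
        p = replace(params, **dict(zip(keys, combo)))
        row: dict[str, float] = dict(zip(keys, combo))
        row["ls_lp_ratio"] = p.L_s / p.L_p
        row["e_c"] = compression_efficiency(p.r_c, sum(p.sizes()), p.S_T)
        row["d_ideal"] = 1.0 / p.a
        for m in methods:
            row[f"Sb_{m}"] = sb(m, p)
            row[f"Sd_{m}"] = sd(m, p)
        rows.append(row)
    return pd.DataFrame(rows)
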