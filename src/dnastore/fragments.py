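"""Oligo fragment format: segmentation and order-free reassembly.

A synthesisable fragment lays its fields out 5' to 3' as::

    head_primer | A | address | C | payload | RS | T | tail_primer(s)

* ``head_primer`` / ``tail_primer(s)``: L_p-nt amplification sites. Data
  fragments carry one tail primer; a tool fragment shared by n client
  files (one-to-many indexing) carries the n client reverse primers.
* ``A`` / ``T``: literal direction markers at the payload boundaries.
* ``address``: the fragment's 0-based index in its stream, a big-endian
  quaternary integer over ``L_addr`` nt (A=0, C=1, G=2, T=3).
* ``C``: one-nt class flag, A = data file, T = tool file, so a sequencing
  run that amplified both classes at once can separate them.
* ``RS``: reserved error-correction field, zero-length by default.

The primer budget of a fragment is fixed by the synthesis length L_s:
ordinary fragments keep ``L_s - 2 L_p`` nt between their two primers, a
shared tool fragment only ``L_s - (n+1) L_p``. Address, class flag and RS
live inside that budget, so the net data payload per fragment is
``capacity - L_addr - 1 - rs_len``. Every fragment of a stream has the
same total length (the last payload is A-padded); the true stream length
in nt is index metadata kept outside the pool, and reassembly trims the
padding with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import (
    AddressOverflowError,
    AssemblyConflictError,
    AssemblyGapError,
    CapacityError,
    FormatError,
)

DIR_HEAD = "A"
DIR_TAIL = "T"
DATA_FLAG = "A"
TOOL_FLAG = "T"

ROLE_DATA = "data"
ROLE_MCI_TOOL = "mci-tool"

_BASE_VAL = {"A": 0, "C": 1, "G": 2, "T": 3}
_VAL_BASE = "ACGT"


def payload_capacity(L_s: int, L_p: int, role: str = ROLE_DATA,
                     n: int = 1) -> int:
    """Nucleotides left for addressed content after the primer blocks.

    Ordinary fragments (data files, or tool files stored under their own
    primer pair) keep ``L_s - 2 L_p``; a one-to-many tool fragment shared
    by *n* data files keeps ``L_s - (n+1) L_p`` (universal head primer
    plus n client tails). Raises :class:`CapacityError` when nothing is
    left.
    """
    if L_s <= 0 or L_p <= 0:
        raise ValueError("L_s and L_p must be positive")
    if role == ROLE_DATA:
        cap = L_s - 2 * L_p
    elif role == ROLE_MCI_TOOL:
        if n < 1:
            raise ValueError("shared-file count n must be >= 1")
        cap = L_s - (n + 1) * L_p
    else:
        raise ValueError(f"unknown fragment role {role!r}")
    if cap <= 0:
        raise CapacityError(
            f"no payload capacity at L_s={L_s}, L_p={L_p}, role={role}, "
            f"n={n}")
    return cap


def encode_address(index: int, l_addr: int) -> str:
    if index < 0 or index >= 4 ** l_addr:
        raise AddressOverflowError(
            f"address {index} does not fit in {l_addr} nt")
    digits = []
    v = index
    for _ in range(l_addr):
        digits.append(_VAL_BASE[v & 3])
        v >>= 2
    return "".join(reversed(digits))


def decode_address(seq: str) -> int:
    v = 0
    for ch in seq:
        try:
            v = (v << 2) | _BASE_VAL[ch]
        except KeyError:
            raise FormatError(f"invalid address symbol {ch!r}") from None
    return v


@dataclass(frozen=True)
class FragmentLayout:
    """Geometry shared by every fragment of one stream."""

    L_s: int = 220
    L_p: int = 20
    L_addr: int = 8
    rs_len: int = 0
    role: str = ROLE_DATA
    n_shared: int = 1

    @property
    def capacity(self) -> int:
        return payload_capacity(self.L_s, self.L_p, self.role, self.n_shared)

    @property
    def data_per_fragment(self) -> int:
        net = self.capacity - self.L_addr - 1 - self.rs_len
        if net <= 0:
            raise CapacityError(
                f"address ({self.L_addr} nt), class flag and RS "
                f"({self.rs_len} nt) leave no payload in a "
                f"{self.capacity}-nt capacity")
        return net

    @property
    def n_tails(self) -> int:
        return 1 if self.role == ROLE_DATA else self.n_shared

    @property
    def fragment_length(self) -> int:
        return (self.L_p + 1 + self.L_addr + 1 + self.data_per_fragment
                + self.rs_len + 1 + self.n_tails * self.L_p)


def layout_for(stream_nt: int, L_s: int = 220, L_p: int = 20,
               role: str = ROLE_DATA, n_shared: int = 1,
               rs_len: int = 0) -> FragmentLayout:
    """Smallest-address layout able to index a *stream_nt*-long stream."""
    cap = payload_capacity(L_s, L_p, role, n_shared)
    for l_addr in range(1, 33):
        net = cap - l_addr - 1 - rs_len
        if net <= 0:
            break
        n_frag = max(1, math.ceil(stream_nt / net))
        if n_frag <= 4 ** l_addr:
            return FragmentLayout(L_s, L_p, l_addr, rs_len, role, n_shared)
    raise AddressOverflowError(
        f"no address width can index a {stream_nt}-nt stream at "
        f"L_s={L_s}, L_p={L_p}, role={role}, n={n_shared}")


@dataclass(frozen=True)
class Fragment:
    head_primer: str
    address: int
    c_flag: str
    payload: str  # padded to the layout's per-fragment payload size
    rs: str
    tail_primers: tuple[str, ...]
    l_addr: int

    def to_seq(self) -> str:
        return (self.head_primer + DIR_HEAD
                + encode_address(self.address, self.l_addr)
                + self.c_flag + self.payload + self.rs + DIR_TAIL
                + "".join(self.tail_primers))

    @classmethod
    def parse(cls, seq: str, layout: FragmentLayout) -> "Fragment":
        if len(seq) != layout.fragment_length:
            raise FormatError(
                f"fragment length {len(seq)} does not match layout "
                f"length {layout.fragment_length}")
        L_p, l_addr = layout.L_p, layout.L_addr
        pos = L_p
        if seq[pos] != DIR_HEAD:
            raise FormatError("missing 5' direction marker")
        pos += 1
        address = decode_address(seq[pos:pos + l_addr])
        pos += l_addr
        c_flag = seq[pos]
        if c_flag not in (DATA_FLAG, TOOL_FLAG):
            raise FormatError(f"invalid class flag {c_flag!r}")
        pos += 1
        payload = seq[pos:pos + layout.data_per_fragment]
        pos += layout.data_per_fragment
        rs = seq[pos:pos + layout.rs_len]
        pos += layout.rs_len
        if seq[pos] != DIR_TAIL:
            raise FormatError("missing 3' direction marker")
        pos += 1
        tails = tuple(seq[pos + i * L_p: pos + (i + 1) * L_p]
                      for i in range(layout.n_tails))
        return cls(seq[:L_p], address, c_flag, payload, rs, tails, l_addr)


def segment(long_dna: str, layout: FragmentLayout, head: str,
            tails: Sequence[str], c_flag: str) -> list[Fragment]:
    """Split an encoded stream into addressed fragments.

    Payloads concatenated in address order reproduce *long_dna* exactly
    (the final fragment is A-padded to full length; callers record the
    true nt length to trim on reassembly). Empty input gives an empty
    fragment list.
    """
    if c_flag not in (DATA_FLAG, TOOL_FLAG):
        raise ValueError(f"invalid class flag {c_flag!r}")
    if len(head) != layout.L_p or any(len(t) != layout.L_p for t in tails):
        raise ValueError("primer lengths must equal layout L_p")
    if len(tails) != layout.n_tails:
        raise ValueError(
            f"layout expects {layout.n_tails} tail primers, got {len(tails)}")
    per = layout.data_per_fragment
    if not long_dna:
        return []
    n_frag = math.ceil(len(long_dna) / per)
    if n_frag > 4 ** layout.L_addr:
        raise AddressOverflowError(
            f"{n_frag} fragments exceed the {4 ** layout.L_addr}-address "
            f"space of a {layout.L_addr}-nt address field")
    rs = "A" * layout.rs_len
    out = []
    tails = tuple(tails)
    for i in range(n_frag):
        chunk = long_dna[i * per:(i + 1) * per]
        out.append(Fragment(head, i, c_flag, chunk.ljust(per, "A"), rs,
                            tails, layout.L_addr))
    return out


def _assemble_class(frags: list[Fragment], nt_length: int | None,
                    c_flag: str) -> str:
    by_addr: dict[int, str] = {}
    for f in frags:
        seen = by_addr.get(f.address)
        if seen is not None and seen != f.payload:
            raise AssemblyConflictError(
                f"address {f.address} ({c_flag}-class) has two different "
                "payloads")
        by_addr[f.address] = f.payload
    if not by_addr:
        if nt_length:
            raise AssemblyGapError(range(1), c_flag=c_flag)
        return ""
    per = len(next(iter(by_addr.values())))
    if nt_length is None:
        expected = max(by_addr) + 1
    else:
        expected = max(1, math.ceil(nt_length / per))
        beyond = [a for a in by_addr if a >= expected]
        if beyond:
            raise AssemblyConflictError(
                f"addresses {sorted(beyond)} lie beyond the declared "
                f"{nt_length}-nt stream extent")
    missing = set(range(expected)) - set(by_addr)
    if missing:
        raise AssemblyGapError(missing, c_flag=c_flag)
    joined = "".join(by_addr[a] for a in range(expected))
    return joined if nt_length is None else joined[:nt_length]


def assemble(fragments: Iterable[Fragment],
             data_nt: int | None = None,
             tool_nt: int | None = None) -> tuple[str, str]:
    """Rebuild the (data-class, tool-class) long sequences from fragments.

    Order-independent: fragments are sorted by decoded address within each
    class. ``data_nt`` / ``tool_nt`` give the true stream lengths so the
    final fragment's padding can be trimmed; without them the padded
    concatenation is returned. Missing addresses raise
    :class:`AssemblyGapError` naming the gaps; a duplicated address with a
    conflicting payload raises :class:`AssemblyConflictError`.
    """
    data = [f for f in fragments if f.c_flag == DATA_FLAG]
    tool = [f for f in fragments if f.c_flag == TOOL_FLAG]
    return (_assemble_class(data, data_nt, DATA_FLAG),
            _assemble_class(tool, tool_nt, TOOL_FLAG))
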