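"""Plant-style miRNA target-site scanning with a complementarity penalty.

A miRNA is aligned antiparallel against every candidate site window of a
transcript.  Per alignment column the penalty is

* Watson-Crick pair: 0
* G:U wobble:        0.5
* mismatch:          1.0
* gap:               2.0

and any penalty falling at miRNA positions 2-13 (counted from the miRNA
5' end -- the seed-extended region) is doubled.  At most one gap is
allowed, so a site window is m-1, m or m+1 nt long for an m-nt miRNA.
The site penalty is the minimum over all admissible alignments; hits at
or below the cutoff (default 4.0) are reported.

Gap conventions (the scheme leaves these open; fixed here and mirrored
by the brute-force oracle in the test suite): an unpaired miRNA base
(site is m-1 nt) is penalized at that base's own position and may sit at
either end; a bulged target base (site is m+1 nt) must be internal and
inherits the position of the miRNA base following it 5'-ward, i.e. the
alignment column it occupies.

circRNA sequences are scanned as circles: the sequence is doubled so
sites spanning the back-splice junction are seen, and hits are
deduplicated modulo the sequence length.

T and U are interchangeable on input; positions are 1-based on the
target 5'->3' sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from ._util import to_rna

GAP_PENALTY = 2.0
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
SEED_RANGE = (2, 13)  # miRNA positions with doubled penalties, inclusive
DEFAULT_MAX_PENALTY = 4.0

_ALPHABET = "ACGU"
_CODE = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT_RNA = {"A": "U", "C": "G", "G": "C", "U": "A"}

# pairwise penalty lookup: [miRNA base, target base]
_PEN = np.full((5, 5), MISMATCH_PENALTY)
for _b, _c in _COMPLEMENT_RNA.items():
    _PEN[_CODE[_b], _CODE[_c]] = 0.0
_PEN[_CODE["G"], _CODE["U"]] = WOBBLE_PENALTY
_PEN[_CODE["U"], _CODE["G"]] = WOBBLE_PENALTY
_PEN[4, :] = 1e9  # 'N'/separator: never part of a hit
_PEN[:, 4] = 1e9


@dataclass
class TargetHit:
    mirna_id: str
    target_id: str
    target_class: str  # mRNA | lncRNA | circRNA
    start: int         # 1-based on the target 5'->3' sequence
    site_length: int
    penalty: float
    alignment: tuple[str, str, str] = ("", "", "")  # miRNA 3'->5', match, target 5'->3'


_TRANS = bytes.maketrans(b"ACGUN", bytes([0, 1, 2, 3, 4]))


def _encode(seq: str) -> np.ndarray:
    raw = to_rna(seq).encode().translate(_TRANS)
    arr = np.frombuffer(raw, dtype=np.uint8)
    if arr.size and arr.max() > 4:
        bad = sorted({chr(c) for c in arr[arr > 4]})
        raise ValueError(f"invalid sequence characters {bad}")
    return arr


def _weights(m: int) -> np.ndarray:
    """Per-column weight for a reversed miRNA: column j holds miRNA position m-j."""
    pos = m - np.arange(m)
    return np.where((pos >= SEED_RANGE[0]) & (pos <= SEED_RANGE[1]), 2.0, 1.0)


def score_duplex(mirna: str, site: str) -> tuple[float, tuple[str, str, str]]:
    """Best (minimum) penalty alignment of a miRNA against one site.

    ``site`` must be m-1, m or m+1 nt long; the returned alignment is
    (miRNA 3'->5' with gaps, match line, target 5'->3' with gaps) where
    '|' marks Watson-Crick pairs, 'o' G:U wobbles, '.' mismatches and
    ' ' gap columns.
    """
    mr = to_rna(mirna)
    sr = to_rna(site)
    for s in (mr, sr):
        if set(s) - set(_ALPHABET):
            raise ValueError(f"invalid characters in {s!r}")
    m, L = len(mr), len(sr)
    rev = mr[::-1]
    if L == m:
        gaps: list[tuple[str, int]] = [("none", -1)]
    elif L == m - 1:
        gaps = [("site", g) for g in range(m)]       # unpaired miRNA base at column g
    elif L == m + 1:
        gaps = [("mirna", g) for g in range(1, m)]   # bulged target base before column g
    else:
        raise ValueError("site length must be within 1 nt of the miRNA length")

    best: tuple[float, tuple[str, str, str]] | None = None
    for kind, g in gaps:
        pen = 0.0
        top, mid, bot = [], [], []
        si = 0
        cols: list[tuple[str, str]] = []  # (miRNA char or '-', site char or '-')
        for j in range(m):
            if kind == "mirna" and j == g:
                cols.append(("-", sr[si]))
                si += 1
            if kind == "site" and j == g:
                cols.append((rev[j], "-"))
            else:
                cols.append((rev[j], sr[si]))
                si += 1
        for col_idx, (mc, sc) in enumerate(cols):
            # miRNA position of this column = m - (count of miRNA bases before it)
            n_mirna_before = sum(1 for c in cols[:col_idx] if c[0] != "-")
            pos = m - n_mirna_before
            w = 2.0 if SEED_RANGE[0] <= pos <= SEED_RANGE[1] else 1.0
            if mc == "-" or sc == "-":
                pen += GAP_PENALTY * w
                mark = " "
            else:
                p = _PEN[_CODE[mc], _CODE[sc]]
                pen += p * w
                mark = "|" if p == 0 else ("o" if p == WOBBLE_PENALTY else ".")
            top.append(mc)
            mid.append(mark)
            bot.append(sc)
        aln = ("".join(top), "".join(mid), "".join(bot))
        if best is None or pen < best[0]:
            best = (pen, aln)
    assert best is not None
    return best


def _windows_nogap(t: np.ndarray, r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Penalty of the ungapped alignment for every window start."""
    m, N = r.size, t.size
    W = N - m + 1
    if W <= 0:
        return np.empty(0)
    out = np.zeros(W)
    for j in range(m):
        out += _PEN[r[j], t[j:j + W]] * w[j]
    return out


def _windows_site_gap(t: np.ndarray, r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Best penalty over gap placements for m-1 nt windows (miRNA base unpaired)."""
    m, N = r.size, t.size
    W = N - (m - 1) + 1
    if W <= 0:
        return np.empty(0)
    left = np.zeros((m, W))   # left[g] = sum_{j<g} pen(r_j, t[w+j]) w_j
    acc = np.zeros(W)
    for g in range(1, m):
        acc = acc + _PEN[r[g - 1], t[g - 1:g - 1 + W]] * w[g - 1]
        left[g] = acc
    right = np.zeros((m, W))  # right[g] = sum_{j>g} pen(r_j, t[w+j-1]) w_j
    acc = np.zeros(W)
    for g in range(m - 2, -1, -1):
        acc = acc + _PEN[r[g + 1], t[g:g + W]] * w[g + 1]
        right[g] = acc
    pen = left + right + (GAP_PENALTY * w)[:, None]
    return pen.min(axis=0)


def _windows_mirna_gap(t: np.ndarray, r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Best penalty over internal bulged-target placements for m+1 nt windows."""
    m, N = r.size, t.size
    W = N - (m + 1) + 1
    if W <= 0:
        return np.empty(0)
    left = np.zeros((m, W))
    acc = np.zeros(W)
    for g in range(1, m):
        acc = acc + _PEN[r[g - 1], t[g - 1:g - 1 + W]] * w[g - 1]
        left[g] = acc
    right = np.zeros((m, W))
    acc = np.zeros(W)
    for g in range(m - 1, 0, -1):
        acc = acc + _PEN[r[g], t[g + 1:g + 1 + W]] * w[g]
        right[g - 1] = acc
    # gap column sits at miRNA position m-g (the following miRNA base's column)
    pen = np.full((m, W), np.inf)
    for g in range(1, m):
        pen[g] = left[g] + GAP_PENALTY * w[g] + right[g - 1]
    return pen.min(axis=0)


def _collapse(raw: list[tuple[int, int, float]], mseq: str, scan_seq: str,
              mirna_id: str, target_id: str, target_class: str) -> list[TargetHit]:
    """Collapse overlapping candidate windows of one (miRNA, target) pair
    to the minimum-penalty window (ties: leftmost, then shortest)."""
    raw.sort(key=lambda x: (x[0], x[1]))
    groups: list[list[tuple[int, int, float]]] = []
    cur_end = -1
    for s0, sl, p in raw:
        if groups and s0 <= cur_end:
            groups[-1].append((s0, sl, p))
            cur_end = max(cur_end, s0 + sl - 1)
        else:
            groups.append([(s0, sl, p)])
            cur_end = s0 + sl - 1
    hits = []
    for grp in groups:
        s0, sl, _ = min(grp, key=lambda x: (x[2], x[0], x[1]))
        pen, aln = score_duplex(mseq, scan_seq[s0:s0 + sl])
        hits.append(TargetHit(mirna_id, target_id, target_class,
                              start=s0 + 1, site_length=sl,
                              penalty=pen, alignment=aln))
    return hits


def scan_targets(mirnas: Mapping[str, str],
                 transcripts: Mapping[str, str],
                 target_class: str = "mRNA",
                 max_penalty: float = DEFAULT_MAX_PENALTY,
                 circular: bool = False) -> list[TargetHit]:
    """Scan every transcript for binding sites of every miRNA.

    ``circular=True`` treats each transcript as a circle (circRNAs):
    the sequence is doubled so junction-spanning sites are found, and
    hits are deduplicated modulo the length.  Overlapping hits of one
    (miRNA, target) pair collapse to the minimum-penalty window.  Empty
    inputs yield an empty list.

    For speed all transcripts are concatenated (separated by an ``N``
    sentinel that no hit can cross) and each miRNA is scanned once over
    the concatenation.
    """
    if max_penalty < 0:
        raise ValueError("max_penalty must be >= 0")
    if not mirnas or not transcripts:
        return []
    ids = list(transcripts)
    lens = {tid: len(transcripts[tid]) for tid in ids}
    max_m = max(len(s) for s in mirnas.values())
    pieces, offsets = [], []
    pos = 0
    for tid in ids:
        seq = transcripts[tid]
        if circular:
            seq = seq + seq[:max_m + 1]
        offsets.append(pos)
        pieces.append(seq)
        pos += len(seq) + 1
    concat = "N".join(pieces)
    t = _encode(concat)
    offsets_arr = np.asarray(offsets)

    hits: list[TargetHit] = []
    for mid, mseq in mirnas.items():
        m = len(mseq)
        r = _encode(mseq)[::-1]
        w = _weights(m)
        raw_by_target: dict[str, list[tuple[int, int, float]]] = {}
        for site_len, pens in (
            (m, _windows_nogap(t, r, w)),
            (m - 1, _windows_site_gap(t, r, w)),
            (m + 1, _windows_mirna_gap(t, r, w)),
        ):
            for s0 in np.where(pens <= max_penalty)[0]:
                ti = int(np.searchsorted(offsets_arr, s0, side="right")) - 1
                tid = ids[ti]
                local = int(s0) - offsets[ti]
                L = lens[tid]
                if circular:
                    if local >= L:
                        continue  # duplicate modulo the circle length
                elif local + site_len > L:
                    continue
                raw_by_target.setdefault(tid, []).append(
                    (local, site_len, float(pens[s0])))
        for tid, raw in raw_by_target.items():
            seq = transcripts[tid]
            scan_seq = seq + seq[:max_m + 1] if circular else seq
            hits.extend(_collapse(raw, mseq, scan_seq, mid, tid, target_class))
    hits.sort(key=lambda h: (h.mirna_id, h.target_id, h.start))
    return hits


def hits_by_pair(hits: Iterable[TargetHit]) -> dict[tuple[str, str], list[TargetHit]]:
    out: dict[tuple[str, str], list[TargetHit]] = {}
    for h in hits:
        out.setdefault((h.mirna_id, h.target_id), []).append(h)
    return out
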