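"""Duplex scoring against a brute-force alignment oracle; window scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernapipe._util import revcomp, to_rna
from cernapipe.targeting import scan_targets, score_duplex

# ------------------------------------------------------------- oracle

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def _col_penalty(mirna_base, target_base):
    if mirna_base == "-" or target_base == "-":
        return 2.0
    if _COMP[mirna_base] == target_base:
        return 0.0
    if (mirna_base, target_base) in (("G", "U"), ("U", "G")):
        return 0.5
    return 1.0


def _oracle_score(mirna, site):
    """Independent exhaustive enumeration of all <=1-gap alignments.

    Alignments are built as explicit column lists of the reversed miRNA
    against the site; each column's weight doubles when the miRNA
    position (m - #miRNA bases before the column) lies in 2..13.
    """
    mirna = to_rna(mirna)
    site = to_rna(site)
    m, L = len(mirna), len(site)
    rev = mirna[::-1]
    alignments = []
    if L == m:
        alignments.append(list(zip(rev, site)))
    elif L == m - 1:
        for g in range(m):  # miRNA base at column g unpaired
            cols, si = [], 0
            for j in range(m):
                if j == g:
                    cols.append((rev[j], "-"))
                else:
                    cols.append((rev[j], site[si]))
                    si += 1
            alignments.append(cols)
    elif L == m + 1:
        for g in range(1, m):  # bulged target base before miRNA column g
            cols, si = [], 0
            for j in range(m):
                if j == g:
                    cols.append(("-", site[si]))
                    si += 1
                cols.append((rev[j], site[si]))
                si += 1
            alignments.append(cols)
    else:
        raise AssertionError("oracle: bad site length")
    best = None
    for cols in alignments:
        pen = 0.0
        for idx, (mb, tb) in enumerate(cols):
            n_before = sum(1 for c in cols[:idx] if c[0] != "-")
            pos = m - n_before
            w = 2.0 if 2 <= pos <= 13 else 1.0
            pen += w * _col_penalty(mb, tb)
        best = pen if best is None else min(best, pen)
    return best


# --------------------------------------------------------- score_duplex

def test_perfect_reverse_complement_scores_zero():
    mir = "ACGUACGUACGUACGUACGUA"
    pen, aln = score_duplex(mir, revcomp(mir))
    assert pen == 0.0
    assert set(aln[1]) == {"|"}


def test_single_mismatch_in_seed_region_costs_two():
    """Mismatch at miRNA position 5 (inside the doubled 2-13 window)."""
    mir = "ACGUACGUACGUACGUACGUA"
    site = list(revcomp(mir))
    j = len(mir) - 5  # column pairing miRNA position 5
    site[j] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[j]]
    pen, _ = score_duplex(mir, "".join(site))
    assert pen == 2.0


def test_wobble_outside_seed_costs_half():
    """G:U at miRNA position 15 (outside 2-13) costs 0.5."""
    mir = "ACGUACGUACGUACGUACGUA"
    site = list(to_rna(revcomp(mir)))
    j = len(mir) - 15
    base = to_rna(mir)[15 - 1]
    assert base in "GU", "fixture assumes a wobble-capable base at position 15"
    site[j] = "U" if base == "G" else "G"
    pen, _ = score_duplex(mir, "".join(site))
    assert pen == 0.5


def test_invalid_characters_rejected():
    with pytest.raises(ValueError):
        score_duplex("ACGX" * 5 + "A", "A" * 21)


@settings(deadline=None, max_examples=300, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.sampled_from([-1, 0, 1]))
def test_score_duplex_matches_exhaustive_oracle(seed, delta):
    rng = np.random.default_rng(seed)
    mir = "".join(rng.choice(list("ACGU"), size=21))
    site = "".join(rng.choice(list("ACGU"), size=21 + delta))
    pen, _ = score_duplex(mir, site)
    assert pen == pytest.approx(_oracle_score(mir, site))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_near_complement_matches_oracle(seed):
    """Sites close to the reverse complement (the interesting regime)."""
    rng = np.random.default_rng(seed)
    mir = "".join(rng.choice(list("ACGU"), size=21))
    site = list(revcomp(mir))
    for _ in range(int(rng.integers(0, 4))):
        site[int(rng.integers(0, len(site)))] = str(rng.choice(list("ACGT")))
    if rng.random() < 0.5 and len(site) > 20:
        del site[int(rng.integers(1, len(site) - 1))]
    site = "".join(site)
    pen, _ = score_duplex(mir, site)
    assert pen == pytest.approx(_oracle_score(mir, site))


# --------------------------------------------------------- scan_targets

def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_planted_site_found_at_recorded_position():
    rng = np.random.default_rng(1)
    mir = _random_seq(rng, 21)
    t = _random_seq(rng, 100)
    t = t[:40] + revcomp(mir) + t[61:]
    hits = scan_targets({"m": mir}, {"t": t})
    assert len(hits) == 1
    assert hits[0].start == 41
    assert hits[0].penalty == 0.0


def test_threshold_excludes_expensive_windows():
    rng = np.random.default_rng(2)
    mir = _random_seq(rng, 21)
    t = _random_seq(rng, 80)
    base = scan_targets({"m": mir}, {"t": t}, max_penalty=1e9)
    best = min(h.penalty for h in base)
    below = scan_targets({"m": mir}, {"t": t}, max_penalty=best - 0.25)
    assert all(h.penalty > best - 0.25 for h in below) or below == []


def test_raising_threshold_never_removes_hits():
    rng = np.random.default_rng(3)
    mir = _random_seq(rng, 21)
    transcripts = {f"t{i}": _random_seq(rng, 150) for i in range(5)}
    transcripts["t0"] = transcripts["t0"][:50] + revcomp(mir) + transcripts["t0"][71:]
    loose = {(h.mirna_id, h.target_id, h.start)
             for h in scan_targets({"m": mir}, transcripts, max_penalty=8.0)}
    tight = {(h.mirna_id, h.target_id, h.start)
             for h in scan_targets({"m": mir}, transcripts, max_penalty=4.0)}
    assert tight <= loose


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_reverse_complement_soundness(seed):
    """Planting the exact reverse complement guarantees a penalty-0 hit
    at the planted position."""
    rng = np.random.default_rng(seed)
    mir = _random_seq(rng, 21)
    pos = int(rng.integers(0, 60))
    t = _random_seq(rng, 100)
    t = t[:pos] + revcomp(mir) + t[pos + 21:]
    hits = scan_targets({"m": mir}, {"t": t})
    assert any(h.start == pos + 1 and h.penalty == 0.0 for h in hits)


def test_junction_spanning_site_needs_circular_scan():
    rng = np.random.default_rng(7)
    mir = _random_seq(rng, 21)
    site = revcomp(mir)
    circ = site[10:] + _random_seq(rng, 80) + site[:10]
    linear = scan_targets({"m": mir}, {"c": circ}, max_penalty=0.0)
    circular = scan_targets({"m": mir}, {"c": circ}, max_penalty=0.0,
                            circular=True)
    assert linear == []
    assert len(circular) == 1
    assert circular[0].start == len(circ) - 10 + 1


def test_empty_inputs_give_empty_result():
    assert scan_targets({}, {"t": "ACGT" * 30}) == []
    assert scan_targets({"m": "ACGUACGUACGUACGUACGUA"}, {}) == []
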