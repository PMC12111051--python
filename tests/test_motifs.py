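"""Motif compilation, scanning vs a brute-force oracle, and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakstate.genome import GenomeSequence
from peakstate.intervals import GenomicInterval, NarrowPeak
from peakstate.motifs import (
    MotifClass, MotifMatch, MotifPattern, PatternError, classify_motifs,
    compile_pattern, default_patterns, extend_peaks, filter_blacklist,
    load_patterns, revcomp, scan_peak,
)

# ---------------------------------------------------------------------------
# Independent oracle: enumerate every window of every realized length on
# both strands and test membership position-by-position. Kept deliberately
# separate from the regex machinery it checks.

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_expand(pattern):
    if "N{" not in pattern:
        return [pattern]
    head, rest = pattern.split("N{", 1)
    bounds, tail = rest.split("}", 1)
    a, b = (int(x) for x in bounds.split(","))
    return [head + "N" * k + tail for k in range(a, b + 1)]


def oracle_scan(seq, patterns):
    """Set of (label, offset, strand) by exhaustive window enumeration."""
    seq = seq.upper()
    hits = set()
    for p in patterns:
        for word in oracle_expand(p.pattern):
            L = len(word)
            for off in range(len(seq) - L + 1):
                window = seq[off : off + L]
                if all(s in ORACLE_IUPAC[c] for s, c in zip(window, word)):
                    hits.add((p.label, off, "+"))
                rc = "".join(ORACLE_RC.get(c, "?") for c in reversed(window))
                if all(s in ORACLE_IUPAC[c] for s, c in zip(rc, word)):
                    hits.add((p.label, off, "-"))
    return hits


def as_keys(matches):
    return {(m.pattern_label, m.offset, m.strand) for m in matches}


# ---------------------------------------------------------------------------
# compilation

def test_pd_7mer_matches_both_strands(compiled_defaults):
    cp = next(c for c in compiled_defaults if c.pattern.label == "PD_GTCAYGG")
    assert as_keys(cp.finditer("GTCACGG")) == {("PD_GTCAYGG", 0, "+")}
    # CCGTGAC is the reverse complement of GTCACGG
    assert as_keys(cp.finditer("CCGTGAC")) == {("PD_GTCAYGG", 0, "-")}


def test_hd_gap_expansion(compiled_defaults):
    cp = next(c for c in compiled_defaults if c.pattern.label == "HD_major")
    assert sorted(len(w) for w in cp.words) == [10, 11]
    hits = as_keys(cp.finditer("TAATGGATTA"))
    # the TAAT/ATTA pair is self-reverse-complementary as a pattern
    assert hits == {("HD_major", 0, "+"), ("HD_major", 0, "-")}


def test_subject_n_never_matches(compiled_defaults):
    cp = next(c for c in compiled_defaults if c.pattern.label == "HD_major")
    assert list(cp.finditer("TAATNNATTA")) == []


@pytest.mark.parametrize("bad", ["TAATN{2,}ATTA", "TAATN{2,9}ATTA",
                                 "TAATN{3,2}ATTA", "TAXT", "AN{1,2}CN{1,2}G"])
def test_invalid_patterns_rejected(bad):
    with pytest.raises(PatternError):
        compile_pattern(MotifPattern("x", "PD", bad))


def test_pattern_file_roundtrip(tmp_path):
    p = tmp_path / "pats.yaml"
    p.write_text(
        "- {label: PD_core, domain_class: PD, pattern: TYMYSS}\n"
        "- {label: HD_minor1, domain_class: HD, pattern: 'TAATN{2,3}TTA'}\n"
    )
    pats = load_patterns(str(p))
    assert [q.label for q in pats] == ["PD_core", "HD_minor1"]
    t = tmp_path / "pats.tsv"
    t.write_text("label\tdomain_class\tpattern\nPD_core\tPD\tTYMYSS\n")
    assert load_patterns(str(t))[0].pattern == "TYMYSS"


# ---------------------------------------------------------------------------
# scanning

def test_scan_known_sequence(compiled_defaults):
    matches = scan_peak("AAAAGTCACGGAAAA", compiled_defaults)
    assert as_keys(matches) == oracle_scan(
        "AAAAGTCACGGAAAA", default_patterns())
    assert ("PD_GTCAYGG", 4, "+") in as_keys(matches)


def test_scan_polyA_is_empty(compiled_defaults):
    assert scan_peak("A" * 300, compiled_defaults) == []


def test_scan_output_sorted_and_deduplicated(compiled_defaults):
    matches = scan_peak("TAATGGATTA" + "TCACGG", compiled_defaults)
    keys = [(m.offset, m.strand, m.pattern_label) for m in matches]
    assert keys == sorted(keys)
    assert len(keys) == len(set(keys))


@settings(derandomize=True, max_examples=300)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
def test_scanner_equals_oracle(compiled_defaults, seq):
    assert as_keys(scan_peak(seq, compiled_defaults)) == oracle_scan(
        seq, default_patterns())


@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet="ACGT", min_size=0, max_size=80))
def test_classification_strand_invariant(compiled_defaults, seq):
    fwd = classify_motifs(scan_peak(seq, compiled_defaults))
    rev = classify_motifs(scan_peak(revcomp(seq), compiled_defaults))
    assert fwd == rev


def test_chance_match_probability_matches_closed_form(compiled_defaults):
    """P(>=1 PD 6-mer hit) in W bp of uniform background is
    1 - (1 - 1/128)^(2(W-5)); check by Monte Carlo at W = 300."""
    cp = [c for c in compiled_defaults if c.pattern.label == "PD_core"]
    rng = np.random.default_rng(42)
    n, W = 3_000, 300
    hits = sum(
        bool(scan_peak("".join(rng.choice(list("ACGT"), W)), cp))
        for _ in range(n)
    )
    p_hat = hits / n
    p_exp = 1 - (1 - 1 / 128) ** (2 * (W - 5))
    se = np.sqrt(p_exp * (1 - p_exp) / n)
    assert abs(p_hat - p_exp) < 3 * se


# ---------------------------------------------------------------------------
# classification hierarchy

def _m(domain, off=0):
    return MotifMatch(f"{domain}_x", domain, off, "+", "ACGT")


@pytest.mark.parametrize("matches,expected", [
    ([_m("PD"), _m("PD", 5)], MotifClass.PD),
    ([_m("PD"), _m("HD", 5)], MotifClass.PDHD),
    ([_m("HD")], MotifClass.HD),
    ([], MotifClass.NONE),
])
def test_hierarchical_classification(matches, expected):
    assert classify_motifs(matches) == expected


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.sampled_from(["PD", "HD"]), max_size=6))
def test_classification_total_and_exclusive(domains):
    got = classify_motifs([_m(d, i) for i, d in enumerate(domains)])
    assert got in set(MotifClass)
    expected = {
        (False, False): MotifClass.NONE, (True, False): MotifClass.PD,
        (False, True): MotifClass.HD, (True, True): MotifClass.PDHD,
    }[("PD" in domains, "HD" in domains)]
    assert got == expected


# ---------------------------------------------------------------------------
# peak preprocessing

def test_extend_peaks_flank_and_clamp():
    g = GenomeSequence({"chr1": "A" * 10_000})
    pks = [NarrowPeak("chr1", 1000, 1300, "a", None, ".", 0, -1, -1, 150),
           NarrowPeak("chr1", 50, 200, "b")]
    ea, eb = extend_peaks(pks, 150, g)
    assert (ea.start, ea.end, ea.name) == (850, 1450, "a")
    assert ea.summit == pks[0].summit  # absolute summit preserved
    assert (eb.start, eb.end) == (0, 350)
    assert [(p.start, p.end) for p in extend_peaks(pks, 0, g)] == [
        (1000, 1300), (50, 200)]


def test_blacklist_overlap_is_strict_halfopen():
    peak = GenomicInterval("chr1", 850, 1450, "p")
    overlapping = [GenomicInterval("chr1", 1400, 1600)]
    abutting = [GenomicInterval("chr1", 1450, 1600)]
    assert filter_blacklist([peak], overlapping) == ([], [peak])
    assert filter_blacklist([peak], abutting) == ([peak], [])
    assert filter_blacklist([peak], []) == ([peak], [])
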