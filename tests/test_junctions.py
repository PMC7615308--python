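"""Junction classifier, per-cell counting and ratio estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from ktsquant import (
    AlignedReadRecord,
    Call,
    IsoformCall,
    JunctionSpec,
    add_ratio_columns,
    aggregate_groups,
    classify_read,
    count_cells,
    estimate_ratio,
    simulate_cells,
    wildtype,
)

from conftest import make_read


# ---------------------------------------------------------------------------
# classify_read
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "start, blocks, kwargs, expected",
    [
        # canonical -KTS junction: gap [1000, 2000), 20 nt anchors
        (980, [("M", 20), ("N", 1000), ("M", 20)], {}, Call.MINUS_KTS),
        # +KTS junction: gap [1009, 2000)
        (989, [("M", 20), ("N", 991), ("M", 20)], {}, Call.PLUS_KTS),
        # gap reaching the acceptor from an unexpected donor
        (985, [("M", 20), ("N", 995), ("M", 20)], {}, Call.AMBIGUOUS),
        # matching gap but 5' anchor below min_anchor=6
        (995, [("M", 5), ("N", 1000), ("M", 20)], {}, Call.AMBIGUOUS),
        # matching gap but 3' anchor below min_anchor
        (980, [("M", 20), ("N", 1000), ("M", 5)], {}, Call.AMBIGUOUS),
        # matching gap but low mapq
        (980, [("M", 20), ("N", 1000), ("M", 20)], {"mapq": 10}, Call.AMBIGUOUS),
        # gap not touching the acceptor at all
        (980, [("M", 20), ("N", 500), ("M", 20)], {}, Call.NON_JUNCTION),
        # ungapped read
        (990, [("M", 50)], {}, Call.NON_JUNCTION),
        # wrong chromosome
        (980, [("M", 20), ("N", 1000), ("M", 20)], {"chrom": "chrX"}, Call.NON_JUNCTION),
    ],
)
def test_classify_read_cases(spec, start, blocks, kwargs, expected):
    assert classify_read(make_read(start, blocks, **kwargs), spec) is expected


def test_classify_multi_gap_reads(spec):
    # two gaps, the second ending at the acceptor: evaluate that one
    r = make_read(470, [("M", 20), ("N", 500), ("M", 10), ("N", 1000), ("M", 20)])
    assert classify_read(r, spec) is Call.MINUS_KTS
    # two gaps, neither ending at the acceptor
    r = make_read(470, [("M", 20), ("N", 400), ("M", 10), ("N", 500), ("M", 20)])
    assert classify_read(r, spec) is Call.NON_JUNCTION


def test_contiguous_reads_in_extension_not_plus_by_default(spec):
    # ungapped read covering the whole 9-nt extension
    r = make_read(995, [("M", 30)])
    assert classify_read(r, spec) is Call.NON_JUNCTION
    spec_allow = JunctionSpec(**(spec.to_dict() | {"allow_contiguous_plus": True}))
    assert classify_read(r, spec_allow) is Call.PLUS_KTS


def test_minus_strand_spec(spec_minus):
    # -KTS gap on the minus strand: [acceptor+1, donor+1) = [1001, 2001)
    r = make_read(981, [("M", 20), ("N", 1000), ("M", 20)], strand="-")
    assert classify_read(r, spec_minus) is Call.MINUS_KTS
    # +KTS donor shifted 9 nt down in transcription direction (leftward)
    r = make_read(981, [("M", 20), ("N", 991), ("M", 20)], strand="-")
    assert classify_read(r, spec_minus) is Call.PLUS_KTS


def test_strand_symmetry(spec, spec_minus):
    """Mirroring a plus-strand scenario through a coordinate reflection
    onto the minus strand leaves every call unchanged."""
    pivot = 3001  # reflection x -> pivot - 1 - x maps [1000,2000) donors onto spec_minus
    records, _ = simulate_cells(wildtype(), 50, 30, error_rate=0.2, spec=spec, seed=21)
    for r in records:
        mirrored = AlignedReadRecord(
            read_id=r.read_id,
            cell=r.cell,
            umi=r.umi,
            chrom=r.chrom,
            strand="-",
            start=pivot - r.end,
            blocks=tuple(reversed(r.blocks)),
            mapq=r.mapq,
        )
        assert classify_read(mirrored, spec_minus) is classify_read(r, spec)


def brute_force_classify(r, spec):
    """Independent oracle: rebuild the read's reference footprint base by
    base and string-match it against the two isoform junction footprints."""
    if r.chrom != spec.chrom:
        return Call.NON_JUNCTION
    # per-base occupancy string over the read's genomic extent
    covered = []
    pos = r.start
    for op, n in r.blocks:
        covered.extend([(p, op) for p in range(pos, pos + n)])
        pos += n
    footprint = "".join(op for _, op in covered)
    import re

    gaps = [(m.start(), m.end()) for m in re.finditer("N+", footprint)]
    results = []
    for g0, g1 in gaps:
        gstart = covered[g0][0]
        gend = covered[g1 - 1][0] + 1
        # anchors: runs of M immediately flanking the gap
        m = re.search("M+$", footprint[:g0])
        left = m.end() - m.start() if m else 0
        m = re.match("M+", footprint[g1:])
        right = m.end() - m.start() if m else 0
        results.append((gstart, gend, left, right))
    minus_fp = spec.gap_interval("MINUS_KTS")
    plus_fp = spec.gap_interval("PLUS_KTS")
    at_acc = [
        g
        for g in results
        if (spec.strand == "+" and g[1] == spec.acceptor)
        or (spec.strand == "-" and g[0] == spec.acceptor + 1)
    ]
    if len(at_acc) != 1:
        return Call.NON_JUNCTION
    gstart, gend, left, right = at_acc[0]
    if (gstart, gend) == minus_fp:
        cand = Call.MINUS_KTS
    elif (gstart, gend) == plus_fp:
        cand = Call.PLUS_KTS
    else:
        return Call.AMBIGUOUS
    if left < spec.min_anchor or right < spec.min_anchor or r.mapq < spec.min_mapq:
        return Call.AMBIGUOUS
    return cand


def test_classifier_matches_brute_force_oracle(spec):
    records, _ = simulate_cells(wildtype(), 40, 50, error_rate=0.2, spec=spec, seed=33)
    # add adversarial structures: low mapq, short anchors, off-target gaps
    extra = [
        make_read(995, [("M", 5), ("N", 1000), ("M", 30)]),
        make_read(980, [("M", 20), ("N", 1000), ("M", 20)], mapq=0),
        make_read(100, [("M", 50)]),
        make_read(470, [("M", 20), ("N", 500), ("M", 10), ("N", 1000), ("M", 20)]),
    ]
    for r in records + extra:
        assert classify_read(r, spec) is brute_force_classify(r, spec)


def test_call_partition(spec):
    """Every read gets exactly one of the four calls."""
    records, _ = simulate_cells(wildtype(), 30, 30, error_rate=0.3, spec=spec, seed=4)
    calls = [classify_read(r, spec) for r in records]
    assert len(calls) == len(records)
    assert all(c in Call for c in calls)


def test_negative_block_length_rejected():
    with pytest.raises(ValueError, match="positive"):
        make_read(0, [("M", 10), ("N", -5), ("M", 10)])


# ---------------------------------------------------------------------------
# count_cells
# ---------------------------------------------------------------------------


def _call(cell, call, umi=None, rid="r"):
    return IsoformCall(rid, cell, call, umi)


def test_count_cells_basic():
    calls = [_call("A", Call.PLUS_KTS, rid=f"p{i}") for i in range(5)] + [
        _call("A", Call.MINUS_KTS, rid=f"m{i}") for i in range(5)
    ]
    out = count_cells(calls, dedup_umi=False)
    assert out.loc[0, ["n_plus", "n_minus", "n_ambiguous"]].tolist() == [5, 5, 0]


def test_umi_dedup_majority_and_tie():
    tie = [
        _call("A", Call.PLUS_KTS, umi="U1", rid="r1"),
        _call("A", Call.MINUS_KTS, umi="U1", rid="r2"),
    ]
    majority = [
        _call("A", Call.MINUS_KTS, umi="U2", rid="r3"),
        _call("A", Call.MINUS_KTS, umi="U2", rid="r4"),
        _call("A", Call.PLUS_KTS, umi="U2", rid="r5"),
    ]
    out = count_cells(tie + majority, dedup_umi=True)
    # U1 collapses to AMBIGUOUS (tie), U2 to MINUS (majority)
    assert out.loc[0, ["n_plus", "n_minus", "n_ambiguous"]].tolist() == [0, 1, 1]
    out_raw = count_cells(tie, dedup_umi=False)
    assert out_raw.loc[0, ["n_plus", "n_minus"]].tolist() == [1, 1]


def test_non_junction_excluded_everywhere():
    calls = [_call("A", Call.NON_JUNCTION, rid=f"n{i}") for i in range(3)]
    assert count_cells(calls).empty


def test_labels_merged():
    labels = pd.DataFrame({"cell": ["A", "B"], "genotype": ["WT/WT", "WT/WT"]})
    out = count_cells([_call("A", Call.MINUS_KTS)], cell_labels=labels)
    assert len(out) == 2  # labelled cell with no reads kept at zero counts
    assert out.set_index("cell").loc["B", "n_minus"] == 0


# ---------------------------------------------------------------------------
# estimate_ratio
# ---------------------------------------------------------------------------


def exact_binomial_ci(k, n, alpha=0.05, tol=1e-10):
    """Clopper-Pearson interval by direct bisection on the binomial tails."""

    def search(f, lo, hi):
        while hi - lo > tol:
            mid = (lo + hi) / 2
            lo, hi = (mid, hi) if f(mid) else (lo, mid)
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else search(lambda p: binom.sf(k - 1, n, p) < alpha / 2, 0.0, 1.0)
    upper = 1.0 if k == n else search(lambda p: binom.cdf(k, n, p) >= alpha / 2, 0.0, 1.0)
    return lower, upper


@pytest.mark.parametrize("k, n_plus", [(8, 2), (0, 10), (10, 0), (3, 17), (1, 1)])
def test_clopper_pearson_matches_tail_inversion(k, n_plus):
    est = estimate_ratio(k, n_plus, ci_method="clopper_pearson")
    lo, hi = exact_binomial_ci(k, k + n_plus)
    assert est.ci_low == pytest.approx(lo, abs=1e-6)
    assert est.ci_high == pytest.approx(hi, abs=1e-6)


def test_estimate_ratio_basics():
    est = estimate_ratio(5, 5)
    assert est.minus_fraction == 0.5
    assert est.ci_low <= 0.5 <= est.ci_high
    assert est.n_informative == 10

    undef = estimate_ratio(0, 0)
    assert not undef.defined
    assert np.isnan(undef.minus_fraction)

    with pytest.raises(ValueError):
        estimate_ratio(1, 1, ci_method="wald")


def test_add_ratio_columns_matches_scalar_api():
    counts = pd.DataFrame(
        {"cell": ["A", "B", "C"], "n_plus": [2, 0, 0], "n_minus": [8, 0, 5], "n_ambiguous": [0, 0, 0]}
    )
    out = add_ratio_columns(counts, ci_method="clopper_pearson")
    for _, row in out.iterrows():
        est = estimate_ratio(row.n_minus, row.n_plus, "clopper_pearson")
        if est.defined:
            assert row.minus_fraction == pytest.approx(est.minus_fraction)
            assert row.ci_low == pytest.approx(est.ci_low)
            assert row.ci_high == pytest.approx(est.ci_high)
        else:
            assert np.isnan(row.minus_fraction)


# ---------------------------------------------------------------------------
# aggregate_groups
# ---------------------------------------------------------------------------


def _counts_table(rows):
    df = pd.DataFrame(rows)
    df["n_ambiguous"] = 0
    return df


def test_aggregate_single_group():
    counts = _counts_table(
        [
            {"cell": "A", "sex": "XY", "n_minus": 2, "n_plus": 0},
            {"cell": "B", "sex": "XY", "n_minus": 0, "n_plus": 2},
        ]
    )
    out = aggregate_groups(counts, ["sex"])
    assert len(out) == 1
    assert out.loc[0, "mean_minus_per_cell"] == 1.0
    assert out.loc[0, "pooled_minus_fraction"] == 0.5


def test_aggregate_two_keys_gives_combinations():
    rows = []
    for sex in ("XX", "XY"):
        for stage in ("18ts", "21ts"):
            rows.append({"cell": f"{sex}{stage}", "sex": sex, "stage": stage, "n_minus": 1, "n_plus": 1})
    out = aggregate_groups(_counts_table(rows), ["sex", "stage"])
    assert len(out) == 4
    with pytest.raises(KeyError):
        aggregate_groups(_counts_table(rows), ["genotype"])


def test_pooled_fraction_is_weighted_mean_of_cell_fractions():
    rng = np.random.default_rng(0)
    counts = _counts_table(
        [
            {"cell": f"c{i}", "grp": "g", "n_minus": int(m), "n_plus": int(p)}
            for i, (m, p) in enumerate(zip(rng.integers(0, 20, 50), rng.integers(1, 20, 50)))
        ]
    )
    out = aggregate_groups(counts, ["grp"])
    n = counts["n_minus"] + counts["n_plus"]
    weighted = np.average(counts["n_minus"] / n, weights=n)
    assert out.loc[0, "pooled_minus_fraction"] == pytest.approx(weighted)
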