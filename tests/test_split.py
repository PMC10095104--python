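"""Two-pass ortholog read splitting: scalar formulas, matrix resolution,
repair rules and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xenotx import (
    PassCounts,
    read_pass_counts,
    resolve_matrix,
    split_shared_reads,
)
from xenotx.io import write_count_matrix


def naive_split(n_hs1, n_mm1, n_hs2):
    """Independent scalar transcription of the splitting formulas."""
    shared = max(n_hs2 - n_hs1, 0)
    denom = n_hs1 + n_mm1
    alpha = 0.5 if denom == 0 else n_hs1 / denom
    return alpha, n_hs1 + alpha * shared


@pytest.mark.parametrize(
    "n_hs1,n_mm1,n_hs2,alpha,actual",
    [
        (10, 40, 16, 0.2, 11.2),  # hand evaluation of the formulas
        (0, 40, 5, 0.0, 0.0),
        (10, 0, 16, 1.0, 16.0),
        (0, 0, 6, 0.5, 3.0),
    ],
)
def test_split_shared_reads_examples(n_hs1, n_mm1, n_hs2, alpha, actual):
    a, x, flags = split_shared_reads(n_hs1, n_mm1, n_hs2)
    assert a == pytest.approx(alpha, abs=1e-12)
    assert x == pytest.approx(actual, abs=1e-12)
    assert flags["degenerate_alpha"] == (n_hs1 + n_mm1 == 0 and n_hs2 > n_hs1)


def test_split_negative_input_rejected():
    with pytest.raises(ValueError):
        split_shared_reads(-1, 3, 4)


def test_split_clamps_inconsistent_pass2():
    a, x, flags = split_shared_reads(10, 5, 9)  # pass2 < pass1
    assert flags["clamped_shared"]
    assert x == 10.0  # shared treated as 0


@given(
    n_hs1=st.integers(0, 500),
    n_mm1=st.integers(0, 500),
    shared=st.integers(0, 200),
)
@settings(max_examples=200, derandomize=True)
def test_split_matches_naive_and_bounds(n_hs1, n_mm1, shared):
    n_hs2 = n_hs1 + shared
    a, x, _ = split_shared_reads(n_hs1, n_mm1, n_hs2)
    a0, x0 = naive_split(n_hs1, n_mm1, n_hs2)
    assert a == pytest.approx(a0, abs=1e-12)
    assert x == pytest.approx(x0, abs=1e-12)
    assert 0.0 <= a <= 1.0
    assert n_hs1 - 1e-12 <= x <= n_hs2 + 1e-12


def _random_instance(rng, n_genes=12, n_samples=3):
    hs_genes = [f"H{i}" for i in range(n_genes)]
    mm_genes = [f"m{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    p1h = rng.integers(0, 50, (n_genes, n_samples))
    p1m = rng.integers(0, 50, (n_genes, n_samples))
    shared = rng.integers(0, 30, (n_genes, n_samples))
    hs = PassCounts(
        "human",
        pd.DataFrame(p1h, index=hs_genes, columns=samples),
        pd.DataFrame(p1h + shared, index=hs_genes, columns=samples),
    )
    mm = PassCounts(
        "mouse",
        pd.DataFrame(p1m, index=mm_genes, columns=samples),
        pd.DataFrame(p1m + shared, index=mm_genes, columns=samples),
    )
    orth = pd.DataFrame({"human": hs_genes, "mouse": mm_genes})
    return hs, mm, orth, shared


def test_resolve_matrix_equals_per_entry_loop():
    """Vectorized resolution equals a naive double loop on >=100 instances."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        hs, mm, orth, shared = _random_instance(rng)
        r_hs, r_mm = resolve_matrix(hs, mm, orth)
        for gi, (gh, gm) in enumerate(zip(orth["human"], orth["mouse"])):
            for sj, s in enumerate(hs.samples):
                a, x, _ = split_shared_reads(
                    hs.pass1.iloc[gi, sj], mm.pass1.iloc[gi, sj], hs.pass2.iloc[gi, sj]
                )
                assert r_hs.actual.loc[gh, s] == pytest.approx(x, abs=1e-12)
                am, xm, _ = split_shared_reads(
                    mm.pass1.iloc[gi, sj], hs.pass1.iloc[gi, sj], mm.pass2.iloc[gi, sj]
                )
                assert r_mm.actual.loc[gm, s] == pytest.approx(xm, abs=1e-12)
                alpha_h = r_hs.alpha.loc[gh, s]
                alpha_m = r_mm.alpha.loc[gm, s]
                assert alpha_h + alpha_m == pytest.approx(1.0, abs=1e-12)


def test_resolve_conservation_and_symmetry():
    rng = np.random.default_rng(17)
    hs, mm, orth, shared = _random_instance(rng, n_genes=30)
    r_hs, r_mm = resolve_matrix(hs, mm, orth)
    # conservation: actual_hs + actual_mm = pass1_hs + pass1_mm + shared
    lhs = r_hs.actual.to_numpy() + r_mm.actual.to_numpy()
    rhs = hs.pass1.to_numpy() + mm.pass1.to_numpy() + shared
    np.testing.assert_allclose(lhs, rhs, atol=1e-9)
    # swapping species swaps outputs exactly
    hs_sw = PassCounts("human", mm.pass1.copy(), mm.pass2.copy())
    mm_sw = PassCounts("mouse", hs.pass1.copy(), hs.pass2.copy())
    orth_sw = pd.DataFrame({"human": orth["mouse"], "mouse": orth["human"]})
    r_hs2, r_mm2 = resolve_matrix(hs_sw, mm_sw, orth_sw)
    np.testing.assert_allclose(r_hs2.actual.to_numpy(), r_mm.actual.to_numpy(), atol=1e-12)
    np.testing.assert_allclose(r_mm2.actual.to_numpy(), r_hs.actual.to_numpy(), atol=1e-12)


def test_private_genes_pass_through():
    samples = ["s0"]
    hs = PassCounts(
        "human",
        pd.DataFrame([[5], [7]], index=["A", "B"], columns=samples),
        pd.DataFrame([[5], [7]], index=["A", "B"], columns=samples),
    )
    mm = PassCounts(
        "mouse",
        pd.DataFrame([[9]], index=["x"], columns=samples),
        pd.DataFrame([[9]], index=["x"], columns=samples),
    )
    orth = pd.DataFrame({"human": [], "mouse": []}, dtype=str)
    r_hs, r_mm = resolve_matrix(hs, mm, orth)
    assert (r_hs.actual == hs.pass2).all().all()
    assert (r_mm.actual == mm.pass2).all().all()
    assert r_hs.alpha.isna().all().all()


def test_sample_mismatch_is_hard_error():
    hs = PassCounts(
        "human",
        pd.DataFrame([[1]], index=["A"], columns=["s1"]),
        pd.DataFrame([[1]], index=["A"], columns=["s1"]),
    )
    mm = PassCounts(
        "mouse",
        pd.DataFrame([[1]], index=["a"], columns=["s2"]),
        pd.DataFrame([[1]], index=["a"], columns=["s2"]),
    )
    with pytest.raises(ValueError, match="sample"):
        resolve_matrix(hs, mm, pd.DataFrame({"human": ["A"], "mouse": ["a"]}))


def test_read_pass_counts_roundtrip_and_repairs(tmp_path):
    genes = ["A", "B"]
    p1 = pd.DataFrame([[3, 4], [5, 6]], index=pd.Index(genes, name="gene"), columns=["s1", "s2"])
    p2 = p1 + 2
    write_count_matrix(p1, tmp_path / "p1.tsv")
    write_count_matrix(p2, tmp_path / "p2.tsv")
    pc = read_pass_counts(tmp_path / "p1.tsv", tmp_path / "p2.tsv", "human")
    assert (pc.pass1 == p1).all().all() and (pc.pass2 == p2).all().all()

    # pass2 cell below pass1 is clamped up with a warning count
    p2_bad = p2.copy()
    p2_bad.iloc[0, 0] = p1.iloc[0, 0] - 1
    write_count_matrix(p2_bad, tmp_path / "p2b.tsv")
    pc = read_pass_counts(tmp_path / "p1.tsv", tmp_path / "p2b.tsv", "human")
    assert pc.n_clamped == 1
    assert pc.pass2.iloc[0, 0] == p1.iloc[0, 0]

    # duplicate gene rows are a hard error
    with open(tmp_path / "dup.tsv", "w") as fh:
        fh.write("gene\ts1\nA\t1\nA\t2\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_pass_counts(tmp_path / "dup.tsv", tmp_path / "dup.tsv", "human")
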