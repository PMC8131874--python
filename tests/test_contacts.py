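import numpy as np
import pandas as pd
import pytest

from crosshub.contacts import (ValidPair, bin_contacts, compartment_eigenvector,
                               filter_contacts, ice_balance, intra_matrix,
                               merge_samples, parse_valid_pairs, read_valid_pairs_frame)
from crosshub.genome import ChromSizes, ParseError


@pytest.fixture
def pair_file(tmp_path):
    p = tmp_path / "p.validPairs"
    p.write_text(
        "r1\tchr1\t100\t+\tchr2\t200\t-\n"
        "r2\tchr1\t50000\t+\tchr1\t150000\t-\textra\tcols\tignored\n"
        "r3\tchrX\t100\t+\tchr1\t100\t-\n"
    )
    return p


class TestParseValidPairs:
    def test_one_based_to_zero_based(self, pair_file):
        pairs = list(parse_valid_pairs(pair_file))
        assert pairs[0].pos1 == 99 and pairs[0].pos2 == 199

    def test_extra_columns_ignored(self, pair_file):
        pairs = list(parse_valid_pairs(pair_file))
        assert pairs[1].chrom2 == "chr1" and pairs[1].pos2 == 149_999

    def test_bad_position_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("r1\tchr1\tabc\t+\tchr2\t200\t-\n")
        with pytest.raises(ParseError, match=":1"):
            list(parse_valid_pairs(p))

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("r1\tchr1\t100\n")
        with pytest.raises(ParseError):
            list(parse_valid_pairs(p))

    def test_frame_reader_agrees(self, pair_file):
        df = read_valid_pairs_frame(pair_file)
        pairs = list(parse_valid_pairs(pair_file))
        assert list(df["pos1"]) == [p.pos1 for p in pairs]


class TestBinContacts:
    sizes = ChromSizes([("chr1", 2_000_000), ("chr2", 2_000_000), ("chrX", 500_000)])

    def test_intra_row(self):
        pairs = [ValidPair("r", "chr1", 50_000, "chr1", 150_000)]
        intra, inter, nd = bin_contacts(pairs, self.sizes)
        assert intra.df.loc[(0, 1)].iloc[0] == 1
        assert len(inter.df) == 0 and nd == 0

    def test_inter_row_at_1mb(self):
        pairs = [ValidPair("r", "chr1", 50_000, "chr2", 50_000)]
        intra, inter, nd = bin_contacts(pairs, self.sizes)
        assert len(intra.df) == 0
        # chr1 has 2 inter bins, chr2 bin 0 is global index 2
        assert inter.df.loc[(0, 2)].iloc[0] == 1

    def test_conservation(self):
        rng = np.random.default_rng(0)
        chroms = ["chr1", "chr2", "chrX"]
        pairs = [ValidPair(f"r{i}", rng.choice(chroms), int(rng.integers(0, 400_000)),
                           rng.choice(chroms), int(rng.integers(0, 400_000)))
                 for i in range(500)]
        intra, inter, nd = bin_contacts(pairs, self.sizes)
        assert intra.df.sum().sum() + inter.df.sum().sum() + nd == 500

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        pairs = [ValidPair(f"r{i}", "chr1", int(rng.integers(0, 2_000_000)),
                           "chr2", int(rng.integers(0, 2_000_000))) for i in range(200)]
        a = bin_contacts(pairs, self.sizes)[1].df
        b = bin_contacts(pairs[::-1], self.sizes)[1].df
        assert a.sort_index().equals(b.sort_index())

    def test_key_canonicalized(self):
        pairs = [ValidPair("r", "chr2", 100, "chr1", 100)]
        _, inter, _ = bin_contacts(pairs, self.sizes)
        (i, j), = inter.df.index
        assert i < j

    def test_merge_zero_fill_and_width_check(self):
        p1 = [ValidPair("r", "chr1", 100, "chr2", 100)]
        p2 = [ValidPair("r", "chr1", 1_500_000, "chr2", 100)]
        _, t1, _ = bin_contacts(p1, self.sizes, sample="a")
        _, t2, _ = bin_contacts(p2, self.sizes, sample="b")
        merged = merge_samples([t1, t2])
        assert merged.df.shape == (2, 2)
        assert merged.df.to_numpy().sum() == 2
        _, t3, _ = bin_contacts(p1, self.sizes, w_inter=500_000, sample="c")
        with pytest.raises(ValueError):
            merge_samples([t1, t3])


class TestFilterContacts:
    def test_self_pairs_removed(self):
        sizes = ChromSizes([("chr1", 300_000)])
        pairs = [ValidPair("r", "chr1", 10, "chr1", 20),
                 ValidPair("r2", "chr1", 10, "chr1", 150_000)]
        intra, _, _ = bin_contacts(pairs, sizes, exclude=())
        out, report = filter_contacts(intra, 0)
        assert report["removed_self_pairs"] == 1
        assert len(out.df) == 1

    def test_min_total(self):
        sizes = ChromSizes([("chr1", 3_000_000), ("chr2", 3_000_000)])
        pairs = [ValidPair("a", "chr1", 10, "chr2", 20)] * 3 + \
                [ValidPair("b", "chr1", 1_500_000, "chr2", 20)]
        _, inter, _ = bin_contacts(pairs, sizes, exclude=())
        out, report = filter_contacts(inter, min_total=2)
        assert report["removed_low_count"] == 1 and len(out.df) == 1

    def test_all_removed_raises(self):
        sizes = ChromSizes([("chr1", 300_000), ("chr2", 300_000)])
        pairs = [ValidPair("a", "chr1", 10, "chr2", 20)]
        _, inter, _ = bin_contacts(pairs, sizes, exclude=())
        with pytest.raises(ValueError, match="min_total"):
            filter_contacts(inter, min_total=100)


class TestIceBalance:
    def test_constant_matrix_fixed_point(self):
        M = np.full((5, 5), 4.0)
        bal = ice_balance(M)
        assert bal.converged
        np.testing.assert_allclose(bal.weights, bal.weights[0])

    def test_biased_outer_product_rebalanced(self):
        rng = np.random.default_rng(0)
        base = np.ones((6, 6)) + 0.5
        bias = np.array([2.0, 1.0, 0.5, 1.5, 1.0, 3.0])
        M = np.outer(bias, bias) * base
        M = (M + M.T) / 2
        bal = ice_balance(M, tol=1e-10)
        s = bal.matrix.sum(axis=1)
        assert np.std(s) / np.mean(s) < 1e-6

    def test_zero_row_masked(self):
        M = np.eye(4) * 0
        M[:3, :3] = 1.0
        bal = ice_balance(M)
        assert not bal.mask[3]
        assert bal.mask[:3].all()

    def test_asymmetric_rejected(self):
        M = np.arange(9, dtype=float).reshape(3, 3)
        with pytest.raises(ValueError, match="symmetric"):
            ice_balance(M)

    def test_idempotent_on_balanced(self):
        rng = np.random.default_rng(2)
        M = rng.poisson(20, size=(8, 8)).astype(float)
        M = M + M.T
        bal = ice_balance(M, tol=1e-10)
        again = ice_balance(bal.matrix, tol=1e-10)
        np.testing.assert_allclose(again.weights[again.mask], again.weights[again.mask][0],
                                   rtol=1e-6)


def _checkerboard(seed, n=60, enrichment=3.0, depth=50.0):
    rng = np.random.default_rng(seed)
    block = (rng.random(n) < 0.5).astype(int)
    base = np.where(np.equal.outer(block, block), enrichment, 1.0)
    decay = 1.0 / (1 + np.abs(np.subtract.outer(np.arange(n), np.arange(n)))) ** 0.5
    M = rng.poisson(base * decay * depth).astype(float)
    return np.triu(M) + np.triu(M, 1).T, block


class TestCompartments:
    def test_two_block_recovery(self):
        M, block = _checkerboard(0)
        bal = ice_balance(M)
        res = compartment_eigenvector(bal, orientation_track=np.where(block == 1, 1.0, -1.0))
        acc = ((res.e1 > 0).astype(int) == block).mean()
        assert acc >= 0.95
        assert set(res.labels[res.mask]) <= {"A", "B"}

    def test_orientation_flip(self):
        M, block = _checkerboard(1)
        bal = ice_balance(M)
        track = np.where(block == 1, 1.0, -1.0)
        res1 = compartment_eigenvector(bal, orientation_track=track)
        res2 = compartment_eigenvector(bal, orientation_track=-track)
        np.testing.assert_allclose(res1.e1, -res2.e1)

    def test_constant_matrix_error(self):
        M = np.full((10, 10), 5.0)
        bal = ice_balance(M)
        with pytest.raises(ValueError):
            compartment_eigenvector(bal)

    def test_too_few_bins(self):
        M = np.full((3, 3), 1.0)
        with pytest.raises(ValueError, match="4"):
            compartment_eigenvector(ice_balance(M))

    def test_scale_invariance(self):
        M, block = _checkerboard(3)
        track = np.where(block == 1, 1.0, -1.0)
        r1 = compartment_eigenvector(ice_balance(M), track)
        r2 = compartment_eigenvector(ice_balance(M * 7.0), track)
        np.testing.assert_allclose(r1.e1, r2.e1, atol=1e-8)
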