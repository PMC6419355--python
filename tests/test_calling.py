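"""Gene-level escapee calling: worked examples, oracle enumeration, properties."""

import itertools

import pandas as pd
import pytest

from xescape.calling import (
    CallConfig,
    call_gene_phased_isnp,
    call_gene_phased_reads,
    call_gene_pooled,
    call_gene_unphased,
    combine_phased_calls,
    consistency_check,
    escapee_fraction,
    par_detection_rates,
)
from xescape.labeling import BIALLELIC, MATERNAL, MONO_REF, PATERNAL
from xescape.types import Consistency, GeneCall, GeneModel, Status


def unphased_labels(n_biallelic, n_mono, *, n_cells=None, bi_cells=None):
    """A gene's unphased iSNP table with given label counts.

    iSNPs are spread over ``n_cells`` cells round-robin unless explicit
    cell lists are given for the biallelic ones.
    """
    rows = []
    n = n_biallelic + n_mono
    n_cells = n_cells or n
    for i in range(n_biallelic):
        cell = (bi_cells or [f"c{i % n_cells}"])[i % len(bi_cells)] if bi_cells else f"c{i % n_cells}"
        rows.append({"cell": cell, "chrom": "X", "pos": i, "label": BIALLELIC})
    for i in range(n_mono):
        rows.append(
            {"cell": f"c{(n_biallelic + i) % n_cells}", "chrom": "X",
             "pos": n_biallelic + i, "label": MONO_REF}
        )
    return pd.DataFrame(rows)


def phased_labels(items):
    """items: (cell, pos, label, n_mat, n_pat) tuples."""
    rows = [
        {
            "cell": c,
            "chrom": "X",
            "pos": p,
            "label": lab,
            "n1": m,
            "n2": pat,
            "total": m + pat,
        }
        for c, p, lab, m, pat in items
    ]
    return pd.DataFrame(rows)


def phased_counts(items):
    """items: (cell, pos, n_mat, n_pat) tuples."""
    return pd.DataFrame(
        [{"cell": c, "chrom": "X", "pos": p, "n_mat": m, "n_pat": pat}
         for c, p, m, pat in items]
    )


class TestUnphasedProtocol:
    def test_two_of_four_biallelic_is_escapee(self):
        """A gene with 4 iSNPs of which 2 are biallelic: escapee with
        iSNP ratio 0.5, but evidence-poor (fewer than 10 iSNPs)."""
        call = call_gene_unphased(unphased_labels(2, 2), gene_id="USP27X-like")
        assert call.status is Status.ESCAPEE
        assert call.isnp_ratio == pytest.approx(0.5)
        assert call.evidence_poor  # < 10 iSNPs

    def test_single_biallelic_isnp_is_inactivated(self):
        call = call_gene_unphased(unphased_labels(1, 5))
        assert call.status is Status.INACTIVATED

    def test_large_gene_ratio(self):
        """456 iSNPs with 103 biallelic across many cells: escapee with
        ratio 0.226 to 3 d.p. and not evidence-poor."""
        call = call_gene_unphased(unphased_labels(103, 353, n_cells=100))
        assert call.status is Status.ESCAPEE
        assert round(call.isnp_ratio, 3) == 0.226
        assert call.n_isnps == 456
        assert not call.evidence_poor

    def test_empty_gene_not_expressed(self):
        call = call_gene_unphased(pd.DataFrame(columns=["cell", "chrom", "pos", "label"]))
        assert call.status is Status.NOT_EXPRESSED

    def test_adding_biallelic_isnp_never_demotes(self):
        """Monotonicity: appending biallelic evidence cannot flip a gene
        from escapee to inactivated."""
        for n_bi in range(0, 4):
            base = call_gene_unphased(unphased_labels(n_bi, 3))
            more = call_gene_unphased(unphased_labels(n_bi + 1, 3))
            if base.status is Status.ESCAPEE:
                assert more.status is Status.ESCAPEE

    def test_strict_mode_only_shrinks(self):
        """Requiring biallelic support from >= 2 cells can only remove
        escapees: two biallelic iSNPs in ONE cell pass the default rule
        but fail strict mode."""
        one_cell = unphased_labels(2, 2, bi_cells=["c0", "c0"])
        assert call_gene_unphased(one_cell).status is Status.ESCAPEE
        assert call_gene_unphased(one_cell, strict=True).status is Status.INACTIVATED
        two_cells = unphased_labels(2, 2, bi_cells=["c0", "c1"])
        assert call_gene_unphased(two_cells, strict=True).status is Status.ESCAPEE


class TestPhasedISNPProtocol:
    def test_one_paternal_of_two_is_escapee(self):
        """2 iSNPs, 1 paternal: escapee, ratio 0.5; with 32 paternal reads
        in one cell the call is evidence-poor (< 50 reads, single cell)."""
        call = call_gene_phased_isnp(
            phased_labels([("c1", 1, PATERNAL, 0, 32), ("c1", 2, MATERNAL, 25, 0)])
        )
        assert call.status is Status.ESCAPEE
        assert call.isnp_ratio == pytest.approx(0.5)
        assert call.evidence_poor

    def test_all_maternal_is_inactivated(self):
        call = call_gene_phased_isnp(
            phased_labels([("c1", 1, MATERNAL, 20, 0), ("c2", 1, MATERNAL, 15, 0)])
        )
        assert call.status is Status.INACTIVATED

    def test_nineteen_of_twenty_supporting(self):
        items = [(f"c{i}", i, PATERNAL, 0, 80) for i in range(10)]
        items += [(f"c{i}", 10 + i, BIALLELIC, 5, 6) for i in range(9)]
        items += [("c10", 19, MATERNAL, 12, 0)]
        call = call_gene_phased_isnp(phased_labels(items))
        assert call.n_isnps == 20
        assert round(call.isnp_ratio, 3) == 0.950
        assert not call.evidence_poor

    def test_unphased_labels_rejected(self):
        with pytest.raises(ValueError, match="unphased"):
            call_gene_phased_isnp(
                pd.DataFrame(
                    [{"cell": "c", "chrom": "X", "pos": 1, "label": MONO_REF,
                      "n1": 9, "n2": 0, "total": 9}]
                )
            )


class TestPhasedReadsProtocol:
    def test_strong_paternal_gene(self):
        """1652 total reads of which 1640 paternal: escapee, ratio 0.993."""
        call = call_gene_phased_reads(phased_counts([("c1", 1, 12, 1640)]))
        assert call.status is Status.ESCAPEE
        assert round(call.paternal_ratio, 3) == 0.993

    def test_six_paternal_reads_is_below_threshold(self):
        call = call_gene_phased_reads(phased_counts([("c1", 1, 1000, 6)]))
        assert call.status is Status.INACTIVATED

    def test_zero_paternal(self):
        call = call_gene_phased_reads(phased_counts([("c1", 1, 50, 0)]))
        assert call.status is Status.INACTIVATED
        assert call.paternal_ratio == 0.0


class TestPooledProtocol:
    @pytest.mark.parametrize(
        "mat,pat,status",
        [
            (70, 30, Status.ESCAPEE),      # AR 0.3 > 0.1
            (95, 5, Status.INACTIVATED),   # AR 0.05
            (100, 0, Status.INACTIVATED),
        ],
    )
    def test_ar_cut(self, mat, pat, status):
        call = call_gene_pooled(phased_counts([("pool", 1, mat, pat)]))
        assert call.status is status


class TestConsistency:
    def test_opposite_monoallelic_in_one_cell_is_inconsistent(self):
        labels = phased_labels(
            [("c1", 1, MATERNAL, 20, 0), ("c1", 2, PATERNAL, 0, 20)]
        )
        assert consistency_check(labels) is Consistency.FULLY_INCONSISTENT

    def test_same_parent_twice_is_consistent(self):
        labels = phased_labels(
            [("c1", 1, MATERNAL, 20, 0), ("c1", 2, MATERNAL, 30, 0)]
        )
        assert consistency_check(labels) is Consistency.CONSISTENT

    def test_biallelic_elsewhere_makes_it_partial(self):
        labels = phased_labels(
            [
                ("c1", 1, MATERNAL, 20, 0),
                ("c1", 2, PATERNAL, 0, 20),
                ("c2", 1, BIALLELIC, 10, 10),
            ]
        )
        assert consistency_check(labels) is Consistency.PARTIALLY_INCONSISTENT

    def test_single_isnp_cells_not_testable(self):
        labels = phased_labels([("c1", 1, MATERNAL, 20, 0), ("c2", 2, PATERNAL, 0, 20)])
        assert consistency_check(labels) is Consistency.NOT_TESTABLE


# Count pairs used to realize each label in the enumeration oracle.
_LABEL_COUNTS = {MATERNAL: (10, 0), PATERNAL: (0, 10), BIALLELIC: (5, 5)}


def brute_force_phased(items, read_min=7):
    """Direct transcription of the two phased protocols' definitions:
    iSNP-based escapee iff any iSNP is paternal or biallelic; read-based
    escapee iff summed paternal reads >= read_min."""
    isnp_esc = any(lab in (PATERNAL, BIALLELIC) for _c, _p, lab, _m, _pt in items)
    pat_reads = sum(pt for _c, _p, _lab, _m, pt in items)
    return isnp_esc, pat_reads >= read_min


class TestPhasedProtocolsAgainstEnumeration:
    def test_exhaustive_small_configurations(self):
        """All label/cell assignments with up to 4 iSNPs and 3 cells match a
        brute-force transcription of the protocol definitions; when every
        iSNP is monoallelic the two protocols agree on status."""
        labels3 = (MATERNAL, PATERNAL, BIALLELIC)
        for n in range(1, 5):
            for labs in itertools.product(labels3, repeat=n):
                for cells in itertools.product("abc", repeat=n):
                    items = [
                        (cells[i], i + 1, labs[i], *_LABEL_COUNTS[labs[i]])
                        for i in range(n)
                    ]
                    exp_isnp, exp_reads = brute_force_phased(items)
                    isnp_call = call_gene_phased_isnp(phased_labels(items))
                    reads_call = call_gene_phased_reads(
                        phased_counts(
                            [(c, p, m, pt) for c, p, _l, m, pt in items]
                        )
                    )
                    assert (isnp_call.status is Status.ESCAPEE) == exp_isnp
                    assert (reads_call.status is Status.ESCAPEE) == exp_reads
                    if BIALLELIC not in labs:
                        assert isnp_call.status is reads_call.status


class TestPARRates:
    def make_calls(self, n_detected, n_expressed):
        calls = {}
        for i in range(n_expressed):
            status = Status.ESCAPEE if i < n_detected else Status.INACTIVATED
            calls[f"PAR{i}"] = GeneCall(
                gene_id=f"PAR{i}", protocol="unphased_isnp", status=status, n_isnps=5
            )
        genes = [
            GeneModel(f"PAR{i}", f"PAR{i}", "X", i * 100, i * 100 + 50, is_par=True)
            for i in range(n_expressed)
        ]
        return calls, genes

    @pytest.mark.parametrize(
        "detected,expressed,fn_rate",
        [(3, 10, 0.70), (0, 5, 1.0)],
    )
    def test_false_negative_rate(self, detected, expressed, fn_rate):
        calls, genes = self.make_calls(detected, expressed)
        rates = par_detection_rates(calls, genes)
        assert rates["false_negative_rate"] == pytest.approx(fn_rate)

    def test_detection_rate_nine_of_eleven(self):
        calls, genes = self.make_calls(9, 11)
        rates = par_detection_rates(calls, genes)
        assert round(rates["detection_rate"], 3) == 0.818

    def test_no_expressed_par_is_error(self):
        calls = {"G1": GeneCall(gene_id="G1", protocol="unphased_isnp",
                                status=Status.NOT_EXPRESSED)}
        genes = [GeneModel("G1", "G1", "X", 0, 10, is_par=True)]
        with pytest.raises(ValueError, match="rate undefined"):
            par_detection_rates(calls, genes)


class TestCombineAndFractions:
    def _call(self, gid, protocol, status):
        return GeneCall(gene_id=gid, protocol=protocol, status=status, n_isnps=3)

    def test_intersection_and_union(self):
        isnp = {
            "A": self._call("A", "phased_isnp", Status.ESCAPEE),
            "B": self._call("B", "phased_isnp", Status.ESCAPEE),
            "C": self._call("C", "phased_isnp", Status.INACTIVATED),
        }
        reads = {
            "A": self._call("A", "phased_reads", Status.ESCAPEE),
            "B": self._call("B", "phased_reads", Status.INACTIVATED),
            "C": self._call("C", "phased_reads", Status.ESCAPEE),
        }
        inter = combine_phased_calls(isnp, reads, mode="intersection")
        union = combine_phased_calls(isnp, reads, mode="union")
        esc = lambda calls: {g for g, c in calls.items() if c.status is Status.ESCAPEE}
        assert esc(inter) == {"A"}
        assert esc(union) == {"A", "B", "C"}
        assert esc(inter) <= esc(union)

    def test_escapee_fraction(self):
        calls = {
            "A": self._call("A", "unphased_isnp", Status.ESCAPEE),
            "B": self._call("B", "unphased_isnp", Status.INACTIVATED),
            "C": self._call("C", "unphased_isnp", Status.INACTIVATED),
            "D": self._call("D", "unphased_isnp", Status.NOT_EXPRESSED),
        }
        assert escapee_fraction(calls) == pytest.approx(1 / 3)
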