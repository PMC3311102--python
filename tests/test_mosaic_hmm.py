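"""Diagnostic SNP calling and the ancestry/heterozygosity Viterbi HMMs."""

import numpy as np
import pytest

from haplomosaic.mosaic_hmm import (
    SUBSPECIES,
    HmmParams,
    call_diagnostic_snps,
    het_log_emissions,
    heterozygosity_viterbi,
    subspecies_log_emissions,
    subspecies_viterbi,
    viterbi_path,
)

from conftest import make_matrix


def brute_best_score(log_emit, log_stay, log_switch):
    """Exhaustive path enumeration (vectorized over all k^m paths)."""
    m, k = log_emit.shape
    paths = np.array(np.meshgrid(*([np.arange(k)] * m),
                                 indexing="ij")).reshape(m, -1).T
    emit = log_emit[np.arange(m), paths].sum(axis=1)
    stays = (paths[:, 1:] == paths[:, :-1]).sum(axis=1)
    trans = stays * log_stay + (m - 1 - stays) * log_switch
    return float((emit + trans).max())


def path_score(path, log_emit, log_stay, log_switch):
    s = float(log_emit[np.arange(len(path)), path].sum())
    for a, b in zip(path, path[1:]):
        s += log_stay if a == b else log_switch
    return s


# ---------------------------------------------------------------------------

def labeled_panel(columns, labels):
    """Matrix of code columns plus a strain->subspecies label dict."""
    m = make_matrix(np.asarray(columns).T,
                    strains=[f"s{i}" for i in range(len(columns[0]))])
    return m, {f"s{i}": sub for i, sub in enumerate(labels) if sub}


class TestDiagnosticCalling:
    # 5 labeled strains: 2 domesticus, 2 musculus, 1 castaneus
    LABELS = ["domesticus", "domesticus", "musculus", "musculus", "castaneus"]

    def test_fully_informative(self):
        m, labels = labeled_panel([[1, 1, 0, 0, 0]], self.LABELS)
        (d,) = [d for d in call_diagnostic_snps(m, labels)
                if d.diagnostic_allele == 1]
        assert (d.subspecies, d.informativeness, d.weight) \
            == ("domesticus", "full", 1.0)

    def test_partially_informative(self):
        m, labels = labeled_panel([[0, 0, 1, 0, 0]], self.LABELS)
        (d,) = [d for d in call_diagnostic_snps(m, labels)
                if d.diagnostic_allele == 1]
        assert (d.subspecies, d.informativeness, d.weight) \
            == ("musculus", "partial", 0.5)

    def test_cross_subspecies_not_diagnostic(self):
        m, labels = labeled_panel([[1, 0, 0, 0, 1]], self.LABELS)
        assert [d for d in call_diagnostic_snps(m, labels)
                if d.diagnostic_allele == 1] == []

    def test_both_alleles_can_be_diagnostic(self):
        # allele 1 only in domesticus; allele 0 only in castaneus (others het)
        m, labels = labeled_panel([[1, 1, 2, 2, 0]], self.LABELS)
        subs = {d.subspecies for d in call_diagnostic_snps(m, labels)}
        assert subs == {"domesticus", "castaneus"}

    def test_missing_subspecies_rejected(self):
        m, labels = labeled_panel([[1, 0]], ["domesticus", "musculus"])
        with pytest.raises(ValueError, match="castaneus"):
            call_diagnostic_snps(m, labels)


class TestViterbiCore:
    def test_matches_exhaustive_enumeration_3state(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            m = int(rng.integers(2, 9))
            emit = rng.normal(size=(m, 3)) * 2
            stay, switch = np.log(0.98), np.log(0.01)
            path = viterbi_path(emit, stay, switch)
            assert path_score(path, emit, stay, switch) == pytest.approx(
                brute_best_score(emit, stay, switch), abs=1e-9)

    def test_matches_exhaustive_enumeration_2state(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            m = int(rng.integers(2, 11))
            emit = rng.normal(size=(m, 2)) * 2
            stay, switch = np.log(0.9), np.log(0.1)
            path = viterbi_path(emit, stay, switch)
            assert path_score(path, emit, stay, switch) == pytest.approx(
                brute_best_score(emit, stay, switch), abs=1e-9)


class TestSubspeciesViterbi:
    def panel(self, query_codes):
        """5 labeled reference strains + 1 query strain over m markers.

        Markers alternate diagnostic subspecies dom, mus, cast, dom, ...
        with the query's codes given.
        """
        m = len(query_codes)
        cols = []
        for j in range(m):
            target = SUBSPECIES[j % 3]
            ref = [1 if self.LABELS[i] == target else 0 for i in range(5)]
            cols.append(ref + [query_codes[j]])
        labels = {f"s{i}": self.LABELS[i] for i in range(5)}
        mat = make_matrix(np.asarray(cols).T,
                          strains=[f"s{i}" for i in range(5)] + ["q"])
        return mat, labels

    LABELS = ["domesticus", "domesticus", "musculus", "musculus", "castaneus"]

    def test_consistent_evidence_single_interval(self):
        # query carries the musculus-diagnostic allele at every mus marker
        codes = [1 if j % 3 == 1 else 0 for j in range(9)]
        mat, labels = self.panel(codes)
        diags = call_diagnostic_snps(mat, labels)
        segs = subspecies_viterbi(mat, "q", diags)
        assert [s.label for s in segs] == ["musculus"]

    def test_isolated_contrary_snp_does_not_switch(self):
        # ten domesticus-supporting SNPs with one castaneus SNP inside:
        # switch cost 2*log(rho) dwarfs the single-SNP emission gain
        mat, labels = self.panel([1, 0, 0] * 7)  # dom allele at dom markers
        diags = call_diagnostic_snps(mat, labels)
        # inject: query carries castaneus allele at marker 11 (cast marker)
        mat.calls[mat.strain_index("q"), 11] = 1
        segs = subspecies_viterbi(mat, "q", diags)
        assert [s.label for s in segs] == ["domesticus"]

    def test_strong_evidence_switches(self):
        # 7 supporting SNPs per block: emission gain 7*(log(1-eps) -
        # log(eps/2)) ~ 25.5 nats beats the ~13.8-nat switch cost
        codes = [1, 0, 0] * 7 + [0, 1, 0] * 7  # dom block then mus block
        mat, labels = self.panel(codes)
        diags = call_diagnostic_snps(mat, labels)
        segs = subspecies_viterbi(mat, "q", diags)
        assert [s.label for s in segs] == ["domesticus", "musculus"]
        # boundary at the midpoint between the flanking diagnostic markers
        assert segs[0].bounds.end_pos + 1 == segs[1].bounds.start_pos

    def test_no_informative_calls_rejected(self):
        mat, labels = self.panel([-1] * 6)
        diags = call_diagnostic_snps(mat, labels)
        with pytest.raises(ValueError, match="no informative"):
            subspecies_viterbi(mat, "q", diags)

    def test_equals_enumeration_on_random_instances(self):
        rng = np.random.default_rng(14)
        params = HmmParams()
        for _ in range(10):
            m = int(rng.integers(3, 9))
            codes = rng.integers(-1, 2, size=m).tolist()
            mat, labels = self.panel(codes)
            diags = call_diagnostic_snps(mat, labels)
            idx = sorted({d.marker_index for d in diags})
            calls = mat.calls[mat.strain_index("q"), idx]
            emit = subspecies_log_emissions(calls, diags, idx, params)
            if not np.any(emit != 0.0):
                continue
            stay = np.log1p(-2 * params.rho)
            switch = np.log(params.rho)
            path = viterbi_path(emit, stay, switch)
            assert path_score(path, emit, stay, switch) == pytest.approx(
                brute_best_score(emit, stay, switch), abs=1e-9)


class TestHetViterbi:
    def strain(self, codes):
        return make_matrix(np.asarray([codes]), strains=["w"])

    def test_all_hom_single_inbred_block(self):
        segs = heterozygosity_viterbi(self.strain([0, 1, 0, 1, 0]), "w")
        assert [s.label for s in segs] == ["inbred"]

    def test_all_het_single_block(self):
        segs = heterozygosity_viterbi(self.strain([2] * 5), "w")
        assert [s.label for s in segs] == ["heterozygous"]

    def test_central_het_run_three_blocks(self):
        # analytic sizing at defaults: a het call carries log(0.5/0.01) ~ 3.9
        # nats for the het state, a hom call log(0.99/0.5) ~ 0.68 for inbred,
        # and a switch costs ~13.8, so 8 central het calls (31 nats) justify
        # two switches (27.6) only when each flank holds > 21 hom calls
        codes = [0] * 30 + [2] * 8 + [1] * 30
        segs = heterozygosity_viterbi(self.strain(codes), "w")
        assert [s.label for s in segs] == ["inbred", "heterozygous", "inbred"]
        # boundaries at midpoints between markers 29|30 and 37|38
        assert segs[0].bounds.end_idx == 29
        assert segs[1].bounds.start_idx == 30
        assert segs[1].bounds.end_idx == 37

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            heterozygosity_viterbi(self.strain([-1, -1]), "w")

    def test_missing_emits_equally(self):
        emit = het_log_emissions(np.array([-1]), HmmParams())
        assert emit.tolist() == [[0.0, 0.0]]

    def test_raising_rho_never_reduces_segments(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            codes = rng.choice([0, 1, 2], size=40,
                               p=[0.35, 0.35, 0.3]).tolist()
            m = self.strain(codes)
            counts = [len(heterozygosity_viterbi(
                m, "w", HmmParams(rho=rho))) for rho in (1e-6, 1e-3, 0.05)]
            assert counts == sorted(counts)


def test_segments_tile_and_alternate():
    rng = np.random.default_rng(16)
    codes = rng.choice([0, 2], size=30, p=[0.6, 0.4]).tolist()
    m = make_matrix(np.asarray([codes]), strains=["w"])
    segs = heterozygosity_viterbi(m, "w", HmmParams(rho=0.01))
    for a, b in zip(segs, segs[1:]):
        assert a.label != b.label
        assert a.bounds.end_pos + 1 == b.bounds.start_pos
    assert segs[0].bounds.start_pos == m.markers[0].pos
    assert segs[-1].bounds.end_pos == m.markers[-1].pos
    for s in segs:
        assert 0.0 <= s.mean_posterior_proxy <= 1.0
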