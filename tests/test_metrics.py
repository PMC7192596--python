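"""False-positive metrics, the trained score and the support-ratio screen."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiger.engine import revcomp
from tiger.fixtures import synthetic_metric_vectors
from tiger.mapper import RawCall
from tiger.metrics import (
    MetricVector, build_enrichment_table, delta_int, dinuc_bias, fp_score,
    gene_content_metrics, mono_bias, support_ratio_filter, train_fp_model,
)
from tiger.model import GeneClass, GeneFeature


def _gene(fid, pfam=None, klass=GeneClass.CDS, start=1, end=300):
    return GeneFeature(
        id=fid, replicon_id="r", start=start, end=end, strand="+",
        klass=klass, top_pfam=(pfam, 50.0) if pfam else None,
    )


class TestMonoBias:
    def test_identical_sequences_zero(self):
        assert mono_bias("ACGTACGT", "ACGTACGT") == 0.0

    def test_hand_case(self):
        # element all G/C vs replicon at 50% GC
        assert mono_bias("GCGC", "ACGTACGT") == pytest.approx(0.5)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            mono_bias("NNNN", "ACGT")


def _brute_dinuc_rho(seq):
    """Independent oracle: direct dinucleotide counting on seq + revcomp."""
    s2 = [seq, revcomp(seq)]
    mono = {b: 0 for b in "ACGT"}
    nm = 0
    di = {}
    nd = 0
    for s in s2:
        for b in s:
            mono[b] += 1
            nm += 1
        for i in range(len(s) - 1):
            di[s[i:i + 2]] = di.get(s[i:i + 2], 0) + 1
            nd += 1
    fm = {b: c / nm for b, c in mono.items()}
    rho = {}
    for x in "ACGT":
        for y in "ACGT":
            if fm[x] * fm[y] > 0:
                rho[x + y] = (di.get(x + y, 0) / nd) / (fm[x] * fm[y])
    return rho


class TestDinucBias:
    def test_identical_sequences_zero(self):
        s = "ACGTTGCAACGT"
        assert dinuc_bias(s, s) == 0.0

    @given(
        a=st.text(alphabet="ACGT", min_size=4, max_size=8),
        b=st.text(alphabet="ACGT", min_size=4, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, a, b):
        ra, rb = _brute_dinuc_rho(a), _brute_dinuc_rho(b)
        expected = sum(abs(ra[k] - rb[k]) for k in ra.keys() & rb.keys()) / 16
        assert dinuc_bias(a, b) == pytest.approx(expected, abs=1e-12)

    def test_strand_symmetry(self):
        s, r = "ACGGTTAACCGTAGGCAT", "TTGACCATGGCAACGTTA"
        assert dinuc_bias(s, r) == pytest.approx(dinuc_bias(revcomp(s), r))

    def test_rotation_invariance_on_long_sequence(self):
        """Replicon rotation changes at most one dinucleotide count, a
        negligible perturbation for genome-scale sequences."""
        rng = np.random.default_rng(0)
        rep = "".join(rng.choice(list("ACGT"), size=20_000))
        ige = rep[5_000:9_000]
        rot = rep[7_000:] + rep[:7_000]
        assert dinuc_bias(ige, rep) == pytest.approx(dinuc_bias(ige, rot), abs=1e-3)


class TestGeneContent:
    def test_hand_enrichment_difference(self):
        hk = {"PfA": 2.0, "PfB": 4.0, "PfC": 1.0}
        ige = [_gene("g1", "PfA"), _gene("g2", "PfB")]
        rep = [_gene("r1", "PfC"), _gene("r2", "PfC")]
        h, f, hyp, _ = gene_content_metrics(ige, rep, hk, {})
        assert h == pytest.approx((2.0 + 4.0) / 2 - 1.0)  # = 2.0

    def test_hypothetical_fraction_difference(self):
        ige = [_gene("g1"), _gene("g2")]  # all hypothetical
        rep = [_gene("r1", "PfC"), _gene("r2", "PfC"), _gene("r3", "PfC"),
               _gene("r4")]  # 25% hypothetical
        _, _, hyp, flags = gene_content_metrics(ige, rep, {}, {})
        assert hyp == pytest.approx(0.75)
        assert "no_pfam_genes" in flags  # element has no Pfam-called genes

    def test_identical_gene_sets_all_zero(self):
        genes = [_gene("g1", "PfA"), _gene("g2")]
        h, f, hyp, _ = gene_content_metrics(genes, genes, {"PfA": 1.5}, {"PfA": 0.2})
        assert (h, f, hyp) == (0.0, 0.0, 0.0)


class TestEnrichmentTable:
    def test_ratio_of_counts(self):
        pos = [_gene(f"p{i}", "PfA") for i in range(10)]
        allg = pos + [_gene(f"a{i}", "PfB") for i in range(30)]
        table = build_enrichment_table(pos, allg)
        assert table["PfA"] == pytest.approx(1.0)  # 10/10
        assert table["PfB"] == 0.0                  # only in negatives

    def test_empty_positive_set_all_zero(self):
        allg = [_gene("a1", "PfA")]
        assert build_enrichment_table([], allg) == {"PfA": 0.0}


class TestDeltaInt:
    def test_interior_distance(self):
        g = _gene("i", klass=GeneClass.Y_INT, start=1_500, end=2_500)
        assert delta_int((1_000, 51_000), [g]) == 500

    def test_overhanging_integrase_floors_to_one(self):
        g = _gene("i", klass=GeneClass.Y_INT, start=900, end=2_000)
        assert delta_int((1_000, 51_000), [g]) == 1

    def test_integrase_at_terminus_floors_to_one(self):
        g = _gene("i", klass=GeneClass.Y_INT, start=1_000, end=2_000)
        assert delta_int((1_000, 51_000), [g]) == 1

    def test_no_integrase_is_error(self):
        g = _gene("i", klass=GeneClass.Y_INT, start=90_000, end=91_000)
        with pytest.raises(ValueError):
            delta_int((1_000, 51_000), [g])


@pytest.fixture(scope="module")
def trained():
    vecs, labels, expected = synthetic_metric_vectors(n=400, seed=5)
    model = train_fp_model(list(zip(vecs, labels)), seed=5)
    return vecs, labels, expected, model


class TestFpModel:
    def test_planted_separation_recovered(self, trained):
        vecs, labels, expected, model = trained
        assert model.auroc > 0.95
        coef = model.coefficients / np.linalg.norm(model.coefficients)
        assert abs(float(coef @ expected)) > 0.9

    def test_confirmed_style_passes_negative_style_fails(self, trained):
        vecs, labels, expected, model = trained
        scores_pos = [fp_score(v, model)[0] for v, l in zip(vecs, labels) if l]
        scores_neg = [fp_score(v, model)[0] for v, l in zip(vecs, labels) if not l]
        # confirmed candidates score lower (less false-positive-like)
        assert np.median(scores_pos) < model.cutoff < np.median(scores_neg)

    def test_score_is_monotone_in_each_metric(self, trained):
        """With fixed coefficient signs the linear score is monotone in
        every metric."""
        _, _, _, model = trained
        base = MetricVector(0.05, 0.1, 0.0, 0.0, 0.0, 20_000, 500)
        s0, _ = fp_score(base, model)
        from tiger.metrics import METRIC_NAMES
        for i, name in enumerate(METRIC_NAMES):
            bumped = MetricVector(**{
                n: getattr(base, n) + (10.0 if n == name else 0.0)
                for n in METRIC_NAMES
            })
            s1, _ = fp_score(bumped, model)
            assert (s1 - s0) * np.sign(model.coefficients[i]) > 0 or \
                model.coefficients[i] == 0

    def test_shuffled_labels_give_no_signal_about_true_classes(self):
        """A model trained on shuffled confirmations must be uninformative
        about the planted classes (AUROC ~ 0.5 up to sampling error)."""
        from sklearn.metrics import roc_auc_score

        vecs, labels, _ = synthetic_metric_vectors(n=400, seed=5)
        rng = np.random.default_rng(3)
        shuffled = [bool(x) for x in rng.permutation(np.array(labels))]
        try:
            m = train_fp_model(list(zip(vecs, shuffled)), seed=3)
        except ValueError:
            return  # degenerate hull labelling is an acceptable outcome
        scores = [fp_score(v, m)[0] for v in vecs]
        auroc_true = roc_auc_score([not l for l in labels], scores)
        assert abs(auroc_true - 0.5) < 0.15

    def test_too_few_vectors_rejected(self):
        vecs, labels, _ = synthetic_metric_vectors(n=30, seed=1)
        with pytest.raises(ValueError):
            train_fp_model(list(zip(vecs, labels)))

    def test_json_round_trip(self, trained, tmp_path):
        from tiger.metrics import FpModel

        _, _, _, model = trained
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FpModel.from_json(path)
        v = MetricVector(0.05, 0.1, 0.0, 0.0, 0.0, 20_000, 500)
        assert fp_score(v, back) == fp_score(v, model)


def _rc(left, right, support):
    return RawCall(replicon_id="r", left=left, right=right, dr_len=10,
                   seed=None, side="q1L", support=support,
                   supporting_refs=[], evidence=[])


class TestSupportRatioFilter:
    def test_ple5_like_signal_rejected(self):
        """Many overlapping calls with top support only 3-fold the second
        best indicate recombination by another agent: reject the seed."""
        calls = [_rc(1_000 + 7 * i, 20_000 + 31 * i, 1) for i in range(56)]
        calls += [_rc(5_000, 18_000, 15), _rc(5_200, 18_100, 5)]
        assert support_ratio_filter({"int1": calls}) == {"int1"}

    def test_single_call_never_rejected(self):
        assert support_ratio_filter({"int1": [_rc(1, 10_000, 1)]}) == set()

    def test_high_ratio_few_overlaps_kept(self):
        calls = [_rc(1_000, 20_000, 100), _rc(1_050, 20_050, 1)]
        assert support_ratio_filter({"int1": calls}) == set()
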