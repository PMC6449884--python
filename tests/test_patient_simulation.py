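"""Patient simulators and the synthetic fixture generator."""

import math

import numpy as np
import pytest

from dispheno import (
    AnnotationCorpus,
    SimulationError,
    add_imprecision,
    add_noise,
    build_pmi,
    load_patients,
    make_fixture,
    parse_annotations,
    parse_obo,
    simulate_cohort,
    simulate_optimal,
    toy_fixture,
    write_disease_annotations,
    write_gene_annotations,
    write_obo,
    write_patients,
)


class TestSimulateOptimal:
    def test_full_penetrance_copies_annotation_set(self, toy_corpus):
        patients = simulate_optimal(toy_corpus, "D:0001", n=5, seed=0)
        for p in patients:
            assert p.terms == toy_corpus.disease_to_terms["D:0001"]
            assert set(p.provenance.values()) == {"optimal"}

    def test_zero_penetrance_exhausts_retries(self, toy_onto):
        corpus = AnnotationCorpus(
            gene_to_terms={},
            disease_to_terms={"D:X": frozenset({"T:0003"})},
            frequency={("D:X", "T:0003"): 0.0},
        )
        with pytest.raises(SimulationError, match="non-empty"):
            simulate_optimal(corpus, "D:X", n=1, seed=0, max_retries=10)

    def test_term_count_matches_truncated_binomial_mean(self):
        # 6 phenotypes at penetrance 0.5, conditioned on >= 1 included
        terms = frozenset(f"X:{i}" for i in range(6))
        corpus = AnnotationCorpus(
            gene_to_terms={},
            disease_to_terms={"D:X": terms},
            frequency={("D:X", t): 0.5 for t in terms},
        )
        patients = simulate_optimal(corpus, "D:X", n=2000, seed=3)
        sizes = np.array([len(p.terms) for p in patients])
        n, q = 6, 0.5
        p_empty = q**n
        mean = n * q / (1 - p_empty)
        var = (n * q * (1 - q) + (n * q) ** 2) / (1 - p_empty) - mean**2
        se = math.sqrt(var / len(sizes))
        assert abs(sizes.mean() - mean) < 3 * se

    def test_deterministic_given_seed(self, toy_corpus):
        a = simulate_optimal(toy_corpus, "D:0001", n=3, seed=9)
        b = simulate_optimal(toy_corpus, "D:0001", n=3, seed=9)
        assert [p.terms for p in a] == [p.terms for p in b]

    def test_unknown_disease_errors(self, toy_corpus):
        with pytest.raises(SimulationError):
            simulate_optimal(toy_corpus, "D:9999", n=1, seed=0)


@pytest.fixture(scope="module")
def mid_fixture():
    return make_fixture(60, 10, 8, depth=4, seed=11)


class TestAddNoise:
    def test_half_count_added(self, mid_fixture):
        onto, corpus, _ = mid_fixture
        disease = sorted(corpus.disease_to_terms)[0]
        base = simulate_optimal(corpus, disease, n=1, seed=1)[0]
        noisy = add_noise(base, onto, corpus, seed=2)
        n_opt = len(base.terms)
        assert len(noisy.terms_tagged("noise")) == -(-n_opt // 2)
        assert len(noisy.terms) == n_opt + -(-n_opt // 2)

    def test_noise_disjoint_from_propagated_annotations(self, mid_fixture):
        onto, corpus, _ = mid_fixture
        disease = sorted(corpus.disease_to_terms)[0]
        associated = onto.closure(corpus.disease_to_terms[disease])
        base = simulate_optimal(corpus, disease, n=1, seed=1)[0]
        for seed in range(50):
            noisy = add_noise(base, onto, corpus, seed=seed)
            assert not (noisy.terms_tagged("noise") & associated)

    def test_deterministic_given_seed(self, mid_fixture):
        onto, corpus, _ = mid_fixture
        disease = sorted(corpus.disease_to_terms)[0]
        base = simulate_optimal(corpus, disease, n=1, seed=1)[0]
        assert (
            add_noise(base, onto, corpus, seed=5).terms
            == add_noise(base, onto, corpus, seed=5).terms
        )

    def test_insufficient_pool_errors(self, toy_onto, toy_corpus):
        base = simulate_optimal(toy_corpus, "D:0001", n=1, seed=0)[0]
        with pytest.raises(SimulationError, match="pool"):
            add_noise(base, toy_onto, toy_corpus, seed=0, n_noise=10)


class TestAddImprecision:
    def test_forced_replacement_on_toy(self, toy_onto, toy_corpus):
        base = simulate_optimal(toy_corpus, "D:0001", n=1, seed=0)[0]
        # {T:0003, T:0004}: one term replaced by T:0001 (only non-root ancestor)
        blurred = add_imprecision(base, toy_onto, seed=4, with_noise=False)
        assert blurred.terms_tagged("imprecise") == frozenset({"T:0001"})
        assert len(blurred.terms) == 2

    def test_replacement_is_proper_ancestor(self, mid_fixture):
        onto, corpus, _ = mid_fixture
        disease = sorted(corpus.disease_to_terms)[1]
        base = simulate_optimal(corpus, disease, n=1, seed=7)[0]
        blurred = add_imprecision(base, onto, seed=8, with_noise=False)
        original = base.terms
        for t in blurred.terms_tagged("imprecise"):
            assert t != onto.root
            assert any(t in onto.ancestors(o) for o in original)

    def test_counts_follow_half_ratios(self, mid_fixture):
        onto, corpus, _ = mid_fixture
        disease = sorted(corpus.disease_to_terms)[1]
        base = simulate_optimal(corpus, disease, n=1, seed=7)[0]
        full = add_imprecision(base, onto, seed=8, corpus=corpus, with_noise=True)
        n_opt = len(base.terms)
        n_replaced = len(full.terms_tagged("imprecise"))
        assert n_replaced <= n_opt // 2  # ancestor collisions may reduce it
        n_after_replacement = len(full.terms) - len(full.terms_tagged("noise"))
        assert len(full.terms_tagged("noise")) == math.ceil(0.5 * n_after_replacement)

    def test_provenance_partitions_terms(self, mid_fixture):
        onto, corpus, _ = mid_fixture
        disease = sorted(corpus.disease_to_terms)[2]
        base = simulate_optimal(corpus, disease, n=1, seed=3)[0]
        full = add_imprecision(base, onto, seed=4, corpus=corpus)
        assert set(full.provenance) == set(full.terms)
        tags = set(full.provenance.values())
        assert tags <= {"optimal", "imprecise", "noise"}


class TestMakeFixture:
    def test_pinned_signature_reproduces_toy(self):
        onto, corpus, defs = make_fixture(6, 3, 2, depth=2, seed=0)
        t_onto, t_corpus, t_defs = toy_fixture()
        assert onto.terms == t_onto.terms
        assert onto.edges == t_onto.edges
        assert corpus.gene_to_terms == t_corpus.gene_to_terms
        assert defs == t_defs

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generated_graph_is_valid_and_deterministic(self, seed):
        onto, corpus, _ = make_fixture(40, 6, 5, depth=3, seed=seed)
        onto.validate()  # acyclic, rooted, every term reaches root
        assert onto.most_depth() >= 3
        onto2, corpus2, _ = make_fixture(40, 6, 5, depth=3, seed=seed)
        assert onto2.edges == onto.edges
        assert corpus2.disease_to_terms == corpus.disease_to_terms
        assert corpus2.frequency == corpus.frequency

    def test_infeasible_shape_errors(self):
        with pytest.raises(ValueError):
            make_fixture(1, 1, 1)
        with pytest.raises(ValueError):
            make_fixture(5, 1, 1, depth=10)

    def test_coannotation_knob_controls_association(self):
        """With the correlation knob at 0, the co-occurrence association
        p(a,b) - p(a)p(b) of random term pairs is centered on 0 (raw PMI of
        co-occurring pairs is selection-biased upward even under exact
        independence, so the covariance is the mean-zero statistic); the
        module structure at high knob settings shows up as a clear excess
        of strongly associated pairs."""

        def association(co, seed):
            onto, corpus, _ = make_fixture(120, 60, 40, depth=4, seed=seed,
                                           co_annotation=co)
            pmi = build_pmi(corpus, onto, source="union", mode="raw")
            leaves = sorted(t for t in onto.leaves() if pmi.term_prob(t) > 0)
            deltas = []
            for i, a in enumerate(leaves):
                for b in leaves[i + 1:]:
                    deltas.append(
                        pmi.pair_prob(a, b) - pmi.term_prob(a) * pmi.term_prob(b)
                    )
            return np.array(deltas)

        d0 = association(0.0, seed=21)
        rng = np.random.default_rng(0)
        sample = rng.choice(d0, size=500, replace=False)
        se = sample.std(ddof=1) / math.sqrt(len(sample))
        assert abs(sample.mean()) < 3 * se

        d_hi = association(0.9, seed=21)
        assert (d_hi > 0.02).sum() > 1.5 * (d0 > 0.02).sum()


class TestRoundTrip:
    def test_fixture_roundtrips_through_real_parsers(self, tmp_path):
        onto, corpus, _ = make_fixture(50, 8, 6, depth=4, seed=2)
        write_obo(onto, tmp_path / "f.obo")
        write_gene_annotations(corpus, tmp_path / "g.txt")
        write_disease_annotations(corpus, tmp_path / "d.hpoa")
        onto2 = parse_obo(tmp_path / "f.obo")
        corpus2 = parse_annotations(tmp_path / "g.txt", tmp_path / "d.hpoa", onto2)
        assert onto2.terms == onto.terms
        assert onto2.edges == onto.edges and onto2.root == onto.root
        assert corpus2.gene_to_terms == corpus.gene_to_terms
        assert corpus2.disease_to_terms == corpus.disease_to_terms
        assert corpus2.frequency == corpus.frequency

    def test_patients_file_roundtrip(self, tmp_path, toy_corpus):
        patients = simulate_optimal(toy_corpus, "D:0001", n=3, seed=1)
        write_patients(patients, tmp_path / "p.tsv")
        back = load_patients(tmp_path / "p.tsv")
        assert [(p.id, p.true_target, p.terms) for p in back] == [
            (p.id, p.true_target, p.terms) for p in patients
        ]


def test_cohort_grades_partition_thirds(mid_fixture):
    onto, corpus, _ = mid_fixture
    cohort = simulate_cohort(onto, corpus, n_per_disease=2, seed=5)
    n_dis = len(corpus.disease_to_terms)
    assert len(cohort) == 3 * 2 * n_dis
    grades = {"optimal": 0, "noisy": 0, "noisy_imprecise": 0}
    for p in cohort:
        if "|noisy_imprecise|" in p.id:
            grades["noisy_imprecise"] += 1
        elif "|noisy|" in p.id:
            grades["noisy"] += 1
        else:
            grades["optimal"] += 1
    assert grades == {k: 2 * n_dis for k in grades}
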