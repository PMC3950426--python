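from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chisquare

from motupipe.distances import p_distance
from motupipe.qc import detect_reading_frame, stop_codon_check
from motupipe.synthetic import (
    AnomalySpec,
    HaplogroupSpec,
    SimulationConfig,
    SpeciesSpec,
    evolve,
    generate_dataset,
    random_survey_config,
    sample_ancestor,
    study_like_config,
)


class TestSampleAncestor:
    def test_deterministic_given_seed(self):
        cfg = study_like_config(seed=77)
        a = sample_ancestor(cfg)
        b = sample_ancestor(cfg)
        assert a == b and len(a) == cfg.n_sites

    def test_stop_free(self):
        nt = sample_ancestor(n_codons=500, rng=np.random.default_rng(1))
        assert stop_codon_check(nt, 0) == 0
        assert nt[-3:] not in {"TAA", "TAG", "AGA", "AGG"}  # no terminal stop either

    def test_codon_distribution_is_uniform_over_non_stops(self):
        rng = np.random.default_rng(42)
        nt = sample_ancestor(n_codons=30000, rng=rng)
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        counts: dict[str, int] = {}
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
        assert set(counts) == {
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
        } - {"TAA", "TAG", "AGA", "AGG"}
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01


class TestEvolve:
    def test_exact_distance(self):
        rng = np.random.default_rng(5)
        nt = sample_ancestor(n_codons=217, rng=rng)
        out = evolve(nt, 13, rng)
        d, n = p_distance(nt, out)
        assert n == 651
        assert d == pytest.approx(100.0 * 13 / 651)

    def test_zero_substitutions_is_identity(self):
        rng = np.random.default_rng(5)
        nt = sample_ancestor(n_codons=100, rng=rng)
        assert evolve(nt, 0, rng) == nt

    def test_avoid_stops_holds_over_heavy_mutation(self):
        rng = np.random.default_rng(9)
        nt = sample_ancestor(n_codons=200, rng=rng)
        for _ in range(10):
            out = evolve(nt, 120, rng)
            assert stop_codon_check(out, 0) == 0
            assert p_distance(nt, out)[0] == pytest.approx(100.0 * 120 / 600)

    def test_explicit_sites_are_respected(self):
        rng = np.random.default_rng(3)
        nt = sample_ancestor(n_codons=100, rng=rng)
        sites = [5, 17, 230]
        out = evolve(nt, 3, rng, sites=sites, avoid_stops=False)
        diff = [i for i, (a, b) in enumerate(zip(nt, out)) if a != b]
        assert diff == sites

    def test_third_position_bias(self):
        rng = np.random.default_rng(11)
        nt = sample_ancestor(n_codons=300, rng=rng)
        pos_counts = [0, 0, 0]
        for _ in range(200):
            out = evolve(nt, 30, rng, avoid_stops=False)
            for i, (a, b) in enumerate(zip(nt, out)):
                if a != b:
                    pos_counts[i % 3] += 1
        # expected 1:1:8 → third position carries ~80% of substitutions
        assert pos_counts[2] > 4 * pos_counts[0]
        assert pos_counts[2] > 4 * pos_counts[1]

    def test_too_many_substitutions_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="more substitutions"):
            evolve("ACGACG", 7, rng)


class TestGenerateDataset:
    def test_deterministic_given_seed(self):
        cfg = study_like_config(seed=21)
        d1, t1 = generate_dataset(cfg)
        d2, t2 = generate_dataset(cfg)
        assert [(s.specimen_id, s.nucleotides) for s in d1.sequences] == [
            (s.specimen_id, s.nucleotides) for s in d2.sequences
        ]
        assert t1.to_json() == t2.to_json()

    def test_different_seeds_differ(self):
        d1, _ = generate_dataset(study_like_config(seed=1))
        d2, _ = generate_dataset(study_like_config(seed=2))
        assert d1.sequences[0].nucleotides != d2.sequences[0].nucleotides

    def test_sizes_follow_the_spec(self):
        cfg = study_like_config(seed=4, anomalies=False)
        dataset, truth = generate_dataset(cfg)
        expected_n = sum(
            h.n_specimens for sp in cfg.species for h in sp.haplogroups
        )
        assert len(dataset) == expected_n
        assert truth.n_haplogroups == sum(
            len(sp.haplogroups) for sp in cfg.species
        )
        for sp in cfg.species:
            for g, h in enumerate(sp.haplogroups):
                label = f"{sp.name} Group {g + 1}"
                assert len(truth.partition[label]) == h.n_specimens

    def test_planted_within_group_distances_are_exact(self):
        cfg = study_like_config(seed=8, anomalies=False)
        dataset, truth = generate_dataset(cfg)
        seq = {s.specimen_id: s.nucleotides for s in dataset.sequences}
        for label, members in truth.partition.items():
            expected = truth.expected_within_max(label)
            if expected is None:
                continue
            realized = max(
                p_distance(seq[a], seq[b])[0]
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            )
            assert realized == pytest.approx(expected, abs=1e-9)

    def test_planted_between_group_distances_are_exact(self):
        cfg = study_like_config(seed=8, anomalies=False)
        dataset, truth = generate_dataset(cfg)
        seq = {s.specimen_id: s.nucleotides for s in dataset.sequences}
        labels = [
            (lab, truth.groups[lab]) for lab in truth.partition
        ]
        for i, (la, ga) in enumerate(labels):
            for lb, gb in labels[i + 1 :]:
                if ga.species != gb.species:
                    continue
                lo, hi = truth.expected_between(la, lb)
                cross = [
                    p_distance(seq[a], seq[b])[0]
                    for a in truth.partition[la]
                    for b in truth.partition[lb]
                ]
                assert min(cross) == pytest.approx(lo, abs=1e-9)
                assert max(cross) == pytest.approx(hi, abs=1e-9)

    def test_realized_targets_reported(self):
        cfg = study_like_config(seed=6, anomalies=False)
        _, truth = generate_dataset(cfg)
        multi = [sp for sp in cfg.species if len(sp.haplogroups) > 1]
        assert len(truth.target_report) == sum(len(sp.haplogroups) for sp in multi)
        # radii are integer substitution counts, so realized separations can
        # sit within one substitution (100/L points) of the target
        granularity = 100.0 / cfg.n_sites
        for entry in truth.target_report:
            assert (
                entry["realized_min_to_sibling"]
                >= entry["target_min_to_sibling"] - granularity
            )

    def test_all_sequences_are_clean_coding(self):
        cfg = study_like_config(seed=10, anomalies=False)
        dataset, _ = generate_dataset(cfg)
        for s in dataset.sequences:
            frame, stops = detect_reading_frame(s.nucleotides)
            assert (frame, stops) == (0, 0)

    def test_metadata_is_complete(self):
        cfg = study_like_config(seed=12, anomalies=False)
        dataset, _ = generate_dataset(cfg)
        assert len(dataset.specimens) == len(dataset.sequences)
        for r in dataset.specimens:
            assert r.morphospecies and r.locality and r.catalogue


class TestAnomalies:
    def test_roster_matches_request(self):
        cfg = study_like_config(seed=13)
        _, truth = generate_dataset(cfg)
        assert len(truth.anomalies["stop_codon"]) == 2
        assert len(truth.anomalies["contaminant"]) == 1
        assert len(truth.anomalies["short"]) == 1
        assert not (truth.anomalous_ids & truth.clean_ids)

    def test_stop_codon_sequence_has_internal_stop(self):
        cfg = study_like_config(seed=13)
        dataset, truth = generate_dataset(cfg)
        seq = {s.specimen_id: s.nucleotides for s in dataset.sequences}
        for sid in truth.anomalies["stop_codon"]:
            assert stop_codon_check(seq[sid], 0) >= 1

    def test_short_sequence_is_short(self):
        cfg = study_like_config(seed=13)
        dataset, truth = generate_dataset(cfg)
        seq = {s.specimen_id: s.nucleotides for s in dataset.sequences}
        for sid in truth.anomalies["short"]:
            assert len(seq[sid]) <= 500

    def test_contaminant_sits_inside_a_foreign_morphospecies(self):
        cfg = study_like_config(seed=13)
        dataset, truth = generate_dataset(cfg)
        seq = {s.specimen_id: s.nucleotides for s in dataset.sequences}
        morpho = dataset.morphospecies_of()
        (sid,) = truth.anomalies["contaminant"]
        others = [s for s in seq if s != sid and s in truth.clean_ids]
        nn = min(others, key=lambda o: p_distance(seq[sid], seq[o])[0])
        assert morpho[nn] != morpho[sid]
        assert p_distance(seq[sid], seq[nn])[0] < 2.0

    def test_too_many_anomalies_errors(self):
        cfg = SimulationConfig(
            seed=1,
            species=(
                SpeciesSpec("A", ("P",), (HaplogroupSpec(2, 0.2),)),
                SpeciesSpec("B", ("Q",), (HaplogroupSpec(1, 0.0),)),
            ),
            anomalies=AnomalySpec(n_stop_codon_seqs=5),
        )
        with pytest.raises(ValueError, match="anomalies"):
            generate_dataset(cfg)


class TestConfigValidation:
    def test_infeasible_within_between_geometry_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SpeciesSpec(
                "bad", ("P",),
                (HaplogroupSpec(2, 3.0, 2.0), HaplogroupSpec(2, 0.2, 2.0)),
            )

    def test_too_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="n_codons"):
            SimulationConfig(seed=1, species=(), n_codons=10)

    def test_random_survey_config_is_deterministic_and_valid(self):
        c1 = random_survey_config(seed=31)
        c2 = random_survey_config(seed=31)
        assert c1 == c2
        dataset, truth = generate_dataset(c1)
        assert len(dataset) == sum(len(m) for m in truth.partition.values())

    def test_random_survey_targets_realized_exactly(self):
        cfg = random_survey_config(seed=17)
        _, truth = generate_dataset(cfg)
        for entry in truth.target_report:
            assert entry["realized_min_to_sibling"] == pytest.approx(
                entry["target_min_to_sibling"], abs=100.0 / cfg.n_sites
            )
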