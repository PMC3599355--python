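"""Clade designation, candidate prediction, and the full pipeline."""

import warnings

import pytest

from pessp.records import CurationConfig
from pessp.simulate import SimulationConfig, simulate_family
from pessp.subgroup import (
    minimal_spanning_clade,
    predict_candidates,
    run_pipeline,
)
from pessp.tree import Tree

CATERPILLAR = "((((A:1,B:1)90:1,C:1)80:1,D:1)70:1,(E:1,F:1)60:1);"


class TestMinimalSpanningClade:
    def test_all_leaves_positive_returns_full_set_without_flag(self):
        t = Tree.from_newick(CATERPILLAR)
        pred = minimal_spanning_clade(t, set("ABCDEF"))
        assert pred.clade == frozenset("ABCDEF")
        assert pred.candidates == frozenset()
        assert not pred.non_discriminating

    def test_single_positive_returns_that_leaf(self):
        t = Tree.from_newick(CATERPILLAR)
        pred = minimal_spanning_clade(t, {"C"})
        assert pred.clade == frozenset({"C"})
        assert pred.candidates == frozenset()

    def test_minimal_clade_carries_its_support(self):
        t = Tree.from_newick(CATERPILLAR)
        pred = minimal_spanning_clade(t, {"A", "C"})
        assert pred.clade == frozenset({"A", "B", "C"})
        assert pred.candidates == frozenset({"B"})
        assert pred.support == 80.0

    def test_scattered_positives_flagged_non_discriminating(self):
        t = Tree.from_newick(CATERPILLAR)
        pred = minimal_spanning_clade(t, {"A", "E"})
        # no proper clade contains both A and E (single-leaf complements
        # are not designatable clusters), so the designation is flagged
        assert pred.clade == frozenset("ABCDEF")
        assert pred.non_discriminating

    def test_unknown_positive_id_rejected(self):
        t = Tree.from_newick(CATERPILLAR)
        with pytest.raises(KeyError):
            minimal_spanning_clade(t, {"Z"})

    def test_growing_positives_never_shrinks_the_clade(self):
        t = Tree.from_newick(CATERPILLAR)
        chain = [{"A"}, {"A", "B"}, {"A", "B", "C"}, {"A", "B", "C", "D"}]
        clades = [minimal_spanning_clade(t, p).clade for p in chain]
        for small, big in zip(clades, clades[1:]):
            assert small <= big

    def test_planted_study_geometry_yields_seven_candidates(self):
        fam = simulate_family(SimulationConfig(seed=7))
        pred = minimal_spanning_clade(fam.tree, fam.positives)
        assert pred.clade == fam.subgroup
        assert len(pred.candidates) == 7


class TestPredictCandidates:
    def annotations(self, pred, extra=None):
        ann = {p: "mandelonitrile hydrolase" for p in pred.positives}
        ann.update(extra or {})
        return ann

    def test_high_support_emits_all_candidates(self):
        t = Tree.from_newick(CATERPILLAR)
        pred = minimal_spanning_clade(t, {"A", "C"})
        pred.support = 95.0
        df = predict_candidates(pred, self.annotations(pred), min_support=50.0)
        assert list(df["accession"]) == ["B"]

    def test_low_support_suppresses_with_warning(self):
        t = Tree.from_newick(CATERPILLAR)
        pred = minimal_spanning_clade(t, {"A", "C"})
        pred.support = 40.0
        with pytest.warns(UserWarning, match="below threshold"):
            df = predict_candidates(pred, self.annotations(pred), min_support=50.0)
        assert df.empty

    def test_ranking_follows_identity_to_query(self):
        """Seven candidates at the subgroup identities 58..53 rank by identity."""
        from pessp.datasets import subgroup_candidates
        from pessp.subgroup import SubgroupPrediction

        sub = subgroup_candidates()
        idents = dict(zip(sub["accession"], sub["identity_pct"].astype(float)))
        assert sorted(idents.values(), reverse=True) == [58, 58, 57, 56, 55, 55, 53]
        pred = SubgroupPrediction(
            clade=frozenset(idents) | {"QRY"},
            positives=frozenset({"QRY"}),
            candidates=frozenset(idents),
            support=95.0,
        )
        df = predict_candidates(
            pred, {"QRY": "mandelonitrile hydrolase"}, min_support=50.0,
            identities=idents,
        )
        assert list(df["identity_pct"]) == sorted(idents.values(), reverse=True)
        assert list(df["rank"]) == [1, 2, 3, 4, 5, 6, 7]

    def test_reference_outside_clade_invalidates_designation(self):
        t = Tree.from_newick(CATERPILLAR)
        pred = minimal_spanning_clade(t, {"A", "C"})
        ann = self.annotations(pred, {"E": "mandelonitrile hydrolase"})
        predict_candidates(pred, ann, min_support=0.0)
        assert not pred.valid
        assert pred.outside_references == frozenset({"E"})


class TestPipeline:
    def test_end_to_end_recovers_planted_candidates_at_study_geometry(self):
        cfg = SimulationConfig(seed=7)
        fam = simulate_family(cfg)
        report = run_pipeline(
            fam.records,
            fam.sequences,
            target_function=cfg.target_function,
            bootstrap_n=50,
            seed=cfg.seed,
            curation_cfg=CurationConfig.passthrough(),
        )
        assert report.prediction.candidates == fam.planted_candidates
        assert report.prediction.valid
        assert set(report.candidates["accession"]) == fam.planted_candidates
        assert report.manifest["n_curated"] == 39

    def test_scattered_positives_produce_flag_and_empty_report(self):
        """Labels planted across unrelated clades must not yield predictions."""
        cfg = SimulationConfig(n_taxa=12, subgroup_size=4, n_labeled_positives=2,
                               root_length=120, seed=3)
        fam = simulate_family(cfg)
        # relabel: one genuine positive, one on the far side of the tree
        inside = min(fam.positives)
        outside = max(set(fam.sequences) - fam.subgroup)
        records = []
        for r in fam.records:
            fn = cfg.target_function if r.accession in (inside, outside) else ""
            records.append(
                type(r)(
                    accession=r.accession, organism=r.organism, residues=r.residues,
                    predicted_function="" if fn else "putative nitrilase",
                    defined_function=fn, identity_to_query=r.identity_to_query,
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_pipeline(
                records, fam.sequences, target_function=cfg.target_function,
                bootstrap_n=20, seed=1, curation_cfg=CurationConfig.passthrough(),
            )
        big = report.prediction
        assert big.candidates != fam.planted_candidates
        assert big.non_discriminating or len(big.clade) > cfg.subgroup_size

    def test_rerun_writes_byte_identical_artifacts(self, tmp_path):
        cfg = SimulationConfig(n_taxa=10, subgroup_size=4, n_labeled_positives=2,
                               root_length=100, seed=5)
        fam = simulate_family(cfg)
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            run_pipeline(
                fam.records, fam.sequences, target_function=cfg.target_function,
                bootstrap_n=20, seed=11, curation_cfg=CurationConfig.passthrough(),
                outdir=out,
            )
            outs.append(out)
        for fname in ("msa.afa", "dist.tsv", "nj.nwk", "bootstrap.nwk",
                      "consensus.nwk", "candidates.tsv", "manifest.json"):
            assert (outs[0] / fname).read_bytes() == (outs[1] / fname).read_bytes()

    def test_config_file_entry_point(self, tmp_path):
        import yaml

        from pessp.curation import write_reference_table
        from pessp.subgroup import PipelineConfig, run_pessp

        cfg = SimulationConfig(n_taxa=10, subgroup_size=4, n_labeled_positives=2,
                               root_length=100, seed=2)
        fam = simulate_family(cfg)
        write_reference_table(fam.records, tmp_path / "table.tsv")
        with (tmp_path / "seqs.fa").open("w") as fh:
            for rid, seq in fam.sequences.items():
                fh.write(f">{rid}\n{seq}\n")
        (tmp_path / "run.yaml").write_text(
            yaml.safe_dump(
                {
                    "table": str(tmp_path / "table.tsv"),
                    "fasta": str(tmp_path / "seqs.fa"),
                    "target_function": cfg.target_function,
                    "bootstrap_n": 20,
                    "seed": 4,
                    "curation": "passthrough",
                }
            )
        )
        report = run_pessp(PipelineConfig.from_yaml(tmp_path / "run.yaml"))
        assert report.prediction.candidates == fam.planted_candidates
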