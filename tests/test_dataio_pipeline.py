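"""File formats, fixture ingestion, the end-to-end pipeline, and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from hybridscreen.cli import main as cli_main
from hybridscreen.dataio import (
    load_ncsr_bank,
    read_corpus_jsonl,
    read_item_bank,
    read_response_matrix,
    write_corpus_jsonl,
    write_item_bank,
    write_response_matrix,
)
from hybridscreen.hybrid_bayes import McmcConfig
from hybridscreen.pipeline import RunConfig, run_pipeline, run_pipeline_from_files
from hybridscreen.psm_text import TokenizedDoc
from hybridscreen.synthetic_data import CohortSpec, gen_study


class TestItemBankIo:
    def test_fixture_matches_published_calibration(self, bank):
        assert len(bank) == 21
        c6 = bank.item_ids.index("C6")
        assert bank.alpha[c6] == 1.86 and bank.beta[c6] == -0.55
        assert bank.alpha.mean() == pytest.approx(1.32, abs=0.005)
        assert bank.beta.mean() == pytest.approx(-0.99, abs=0.005)

    def test_roundtrip(self, bank, tmp_path):
        p = tmp_path / "bank.csv"
        write_item_bank(bank, p)
        again = read_item_bank(p)
        assert again.item_ids == bank.item_ids
        assert np.array_equal(again.alpha, bank.alpha)
        assert np.array_equal(again.beta, bank.beta)
        assert np.array_equal(again.validity_r, bank.validity_r)

    def test_unicode_minus_normalized(self, tmp_path):
        p = tmp_path / "bank.csv"
        p.write_text("item_id,alpha,beta\nA1,1.5,−0.75\n")
        assert read_item_bank(p).beta[0] == -0.75

    def test_error_cases(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("item_id,alpha,beta\n")
        with pytest.raises(ValueError, match="no items"):
            read_item_bank(empty)
        dup = tmp_path / "dup.csv"
        dup.write_text("item_id,alpha,beta\nA1,1.0,0.0\nA1,1.2,0.3\n")
        with pytest.raises(ValueError, match="A1"):
            read_item_bank(dup)
        missing = tmp_path / "missing.csv"
        missing.write_text("item_id,alpha\nA1,1.0\n")
        with pytest.raises(ValueError, match="beta"):
            read_item_bank(missing)


class TestCorpusAndResponses:
    def test_corpus_roundtrip_preserves_stems_and_labels(self, tmp_path):
        docs = [TokenizedDoc("p1", ("flashback", "avoid", "fear"), 1),
                TokenizedDoc("p2", ("calm", "funni"), 2)]
        p = tmp_path / "corpus.jsonl"
        write_corpus_jsonl(docs, p)
        again = read_corpus_jsonl(p)
        assert [d.id for d in again] == ["p1", "p2"]
        assert [d.label for d in again] == [1, 2]
        assert again[0].tokens == docs[0].tokens

    def test_response_matrix_roundtrip(self, bank, tmp_path):
        study = gen_study(CohortSpec(n=10, seed=2), bank)
        p = tmp_path / "resp.csv"
        write_response_matrix(study.responses, p)
        again = read_response_matrix(p)
        assert again.person_ids == study.responses.person_ids
        assert np.array_equal(again.values, study.responses.values)


@pytest.fixture(scope="module")
def fast_cfg():
    return RunConfig(mcmc=McmcConfig(n_iter=600, burn_in=200, seed=4))


class TestPipeline:
    def test_report_structure(self, bank, small_study, fast_cfg):
        rep = run_pipeline(small_study.docs, small_study.responses,
                           small_study.is_ptsd, bank, fast_cfg)
        assert set(rep.metrics_by_approach) == {"irt", "text", "hybrid"}
        for row in rep.metrics_by_approach.values():
            assert set(row) == {"accuracy", "sensitivity", "specificity",
                                "ppv", "npv"}
        assert len(rep.se_curve_with) == len(rep.se_curve_without) == 21
        assert rep.ranked_items[0] == "C6"
        assert set(rep.validity) == set(bank.item_ids)

    def test_missing_dependency_named(self, tmp_path):
        cfg = RunConfig(corpus_path=str(tmp_path / "nope.jsonl"),
                        responses_path=str(tmp_path / "nope.csv"))
        with pytest.raises(FileNotFoundError, match="corpus"):
            run_pipeline_from_files(cfg)
        with pytest.raises(ValueError, match="approach 3"):
            run_pipeline_from_files(RunConfig())

    def test_seeded_runs_are_byte_identical(self, bank, tmp_path):
        study = gen_study(CohortSpec(n=30, seed=6), bank)
        outs = []
        for run in ("a", "b"):
            out = tmp_path / run
            write_corpus_jsonl(study.docs, tmp_path / f"corpus_{run}.jsonl")
            write_response_matrix(study.responses, tmp_path / f"resp_{run}.csv")
            cfg = RunConfig(corpus_path=str(tmp_path / f"corpus_{run}.jsonl"),
                            responses_path=str(tmp_path / f"resp_{run}.csv"),
                            out_dir=str(out),
                            mcmc=McmcConfig(n_iter=400, burn_in=100, seed=8))
            run_pipeline_from_files(cfg)
            outs.append((out / "report.json").read_bytes())
        assert outs[0] == outs[1]


class TestCli:
    def test_route_and_simulate_and_score(self, tmp_path):
        runner = CliRunner()
        plan = tmp_path / "plan.json"
        res = runner.invoke(cli_main, ["route", "--out", str(plan)])
        assert res.exit_code == 0, res.output
        assert json.loads(plan.read_text())["ranked_items"][0] == "C6"

        sim = tmp_path / "sim"
        res = runner.invoke(cli_main, ["simulate", "--n", "40", "--seed", "3",
                                       "--out-dir", str(sim)])
        assert res.exit_code == 0, res.output
        assert (sim / "corpus.jsonl").exists() and (sim / "responses.csv").exists()

        scores = tmp_path / "scores.csv"
        res = runner.invoke(cli_main, ["score-text",
                                       "--train", str(sim / "corpus.jsonl"),
                                       "--score", str(sim / "corpus.jsonl"),
                                       "--out", str(scores)])
        assert res.exit_code == 0, res.output
        import pandas as pd

        df = pd.read_csv(scores)
        assert len(df) == 40
        assert df["standardized"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_evaluate_counts(self, tmp_path):
        import pandas as pd

        pd.DataFrame({"person_id": list("abcd"),
                      "positive": [1, 1, 0, 0]}).to_csv(tmp_path / "truth.csv",
                                                        index=False)
        pd.DataFrame({"person_id": list("abcd"),
                      "positive": [1, 0, 0, 1]}).to_csv(tmp_path / "pred.csv",
                                                        index=False)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["evaluate",
                                       "--pred", str(tmp_path / "pred.csv"),
                                       "--truth", str(tmp_path / "truth.csv"),
                                       "--out", str(tmp_path / "m.json")])
        assert res.exit_code == 0, res.output
        payload = json.loads((tmp_path / "m.json").read_text())
        assert payload["counts"] == {"tp": 1, "fp": 1, "tn": 1, "fn": 1}
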