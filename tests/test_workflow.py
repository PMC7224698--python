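"""End-to-end reports and the command-line interface."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from codonstate.errors import ValidationError
from codonstate.synthetic import (
    TranscriptomeSpec,
    generate_fraction_counts,
    generate_transcriptome,
)
from codonstate.workflow import run_codon_report, run_translation_report


@pytest.fixture(scope="module")
def small_study():
    spec = TranscriptomeSpec(seed=13, n_genes=500, length_range=(80, 200))
    return generate_transcriptome(spec)


def test_codon_report_ranks_planted_gene_in_lowest_quartile(small_study):
    records, table, truth = small_study
    report = run_codon_report(records, table, "Eif2ak1")
    assert report["n_genes"] == 500
    q1 = report["distribution_summaries"]["all_genes"]["q1"]
    assert report["cai_median"] <= q1
    assert report["percentile_all"] < 25.0
    assert report["pct_genes_higher"] == pytest.approx(
        100.0 - report["percentile_all"]
    )
    # the planted gene is itself a kinase, so it is ranked in the subset too
    assert report["percentile_subset"] < 25.0
    profile = pd.DataFrame(report["rare_codon_profile"])
    assert profile["n_codons"].sum() > 0
    assert (profile["mean_w"] <= 1.0).all()


def test_codon_report_unknown_gene_lists_near_matches(small_study):
    records, table, _ = small_study
    with pytest.raises(ValidationError, match="near matches"):
        run_codon_report(records, table, "Eif2akk1")


def test_expression_weighted_reference_is_available(small_study):
    records, table, _ = small_study
    plain = run_codon_report(records, table, "Eif2ak1")
    weighted = run_codon_report(records, table, "Eif2ak1", expression_weighted=True)
    assert weighted["parameters"]["expression_weighted"]
    # same gene, same scale, but a different reference pool
    assert 0 < weighted["cai_median"] < 1
    assert weighted["cai_median"] != plain["cai_median"]


def test_translation_report_opposite_shifts_in_one_report():
    hri_control, _ = generate_fraction_counts(0.35, seed=1, noise=False)
    hri_pi, _ = generate_fraction_counts(0.60, seed=2, noise=False)
    actin_control, _ = generate_fraction_counts(0.55, seed=3, noise=False)
    actin_pi, _ = generate_fraction_counts(0.30, seed=4, noise=False)
    report = run_translation_report(
        {
            "Hri": {"control": hri_control, "PI": hri_pi},
            "Actb": {"control": actin_control, "PI": actin_pi},
        }
    )
    assert report["genes"]["Hri"]["shifts"]["PI"]["label"] == "rightward"
    assert report["genes"]["Actb"]["shifts"]["PI"]["label"] == "leftward"
    assert report["genes"]["Hri"]["P"]["control"] == pytest.approx(0.35)

    with pytest.raises(ValidationError, match="control condition missing"):
        run_translation_report({"Hri": {"PI": hri_pi}})


def test_translation_report_invariant_to_row_order():
    df, _ = generate_fraction_counts(0.5, seed=9)
    shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = run_translation_report({"g": {"control": df, "PI": df}})
    b = run_translation_report({"g": {"control": shuffled, "PI": shuffled}})
    assert a["genes"] == b["genes"]


# ---------------------------------------------------------------------------
# CLI

def run_cli(argv):
    from codonstate.cli import main

    try:
        main(argv)
    except SystemExit as exc:
        return exc.code or 0
    return 0


@pytest.fixture(scope="module")
def sim_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    code = run_cli(
        ["simulate", "transcriptome", "--seed", "21", "--out", str(out)]
    )
    assert code == 0
    return out


def test_cli_codon_report_is_byte_identical_across_reruns(sim_dir, tmp_path):
    args = [
        "codon-report",
        "--fasta", str(sim_dir / "transcriptome.fa"),
        "--expression", str(sim_dir / "expression.tsv"),
        "--gene", "Eif2ak1",
    ]
    out1, out2 = tmp_path / "r1", tmp_path / "r2"
    assert run_cli(args + ["--out", str(out1)]) == 0
    assert run_cli(args + ["--out", str(out2)]) == 0
    for name in ("codon_report.json", "weights.csv", "gene_cai.csv",
                 "run_manifest.json"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
    report = json.loads((out1 / "codon_report.json").read_text())
    assert report["gene"] == "Eif2ak1"
    manifest = json.loads((out1 / "run_manifest.json").read_text())
    assert set(manifest["inputs"]) == {
        str(sim_dir / "transcriptome.fa"),
        str(sim_dir / "expression.tsv"),
    }


def test_cli_optimize_and_cai_roundtrip(sim_dir, tmp_path):
    report_dir = tmp_path / "rep"
    assert run_cli([
        "codon-report",
        "--fasta", str(sim_dir / "transcriptome.fa"),
        "--expression", str(sim_dir / "expression.tsv"),
        "--gene", "Eif2ak1",
        "--out", str(report_dir),
    ]) == 0
    weights = report_dir / "weights.csv"
    opt_fa = tmp_path / "opt.fa"
    opt_report = tmp_path / "opt.json"
    assert run_cli([
        "optimize",
        "--fasta", str(sim_dir / "transcriptome.fa"),
        "--weights", str(weights),
        "--out", str(opt_fa),
        "--report", str(opt_report),
    ]) == 0
    opt = json.loads(opt_report.read_text())
    assert all(v["cai_after"] == pytest.approx(1.0) for v in opt.values())

    scores = tmp_path / "cai.csv"
    assert run_cli([
        "cai", "--fasta", str(opt_fa), "--weights", str(weights),
        "--out", str(scores),
    ]) == 0
    df = pd.read_csv(scores)
    assert np.allclose(df["cai"], 1.0)


def test_cli_polysome_and_halflife_subcommands(tmp_path):
    sim = tmp_path / "sim"
    assert run_cli(["simulate", "counts", "--seed", "4", "--out", str(sim)]) == 0
    out = tmp_path / "polysome.json"
    assert run_cli([
        "polysome",
        "--control", str(sim / "counts_control.csv"),
        "--treated", str(sim / "counts_PI.csv"),
        "--gene", "Hri",
        "--out", str(out),
    ]) == 0
    report = json.loads(out.read_text())
    assert report["genes"]["Hri"]["shifts"]["PI"]["label"] == "leftward"

    assert run_cli(["simulate", "pulsechase", "--seed", "4", "--out", str(sim)]) == 0
    hl_out = tmp_path / "halflife.json"
    assert run_cli([
        "halflife", "--series", str(sim / "pulsechase.csv"), "--out", str(hl_out),
    ]) == 0
    hl = json.loads(hl_out.read_text())
    assert hl["control"]["t_half_h"] == pytest.approx(4.2, rel=0.5)

    assert run_cli(["simulate", "trace", "--seed", "4", "--out", str(sim)]) == 0
    assert (sim / "trace_control.csv").exists() and (sim / "trace_PI.csv").exists()


def test_cli_exit_codes_for_missing_input_and_validation_error(tmp_path, sim_dir):
    assert run_cli([
        "codon-report", "--fasta", "no_such.fa",
        "--expression", "none.tsv", "--gene", "X", "--out", str(tmp_path),
    ]) == 3
    assert run_cli([
        "codon-report",
        "--fasta", str(sim_dir / "transcriptome.fa"),
        "--expression", str(sim_dir / "expression.tsv"),
        "--gene", "NotAGene", "--out", str(tmp_path / "x"),
    ]) == 2
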