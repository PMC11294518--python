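"""Provenance recipes: recording, serialization, replay, script generation."""

import hashlib
import subprocess
import sys
from pathlib import Path

import pytest

from geotidy.fixtures import PathologySpec, write_fixture
from geotidy.geo_io import parse_platform_table, parse_series_matrix
from geotidy.recipe import (
    Recipe,
    ReplayError,
    Session,
    bundle_digest,
    generate_script,
    parse_recipe,
    replay,
    serialize_recipe,
)

SPEC = PathologySpec(
    n_samples=6,
    n_features=12,
    pathologies=("key_value_pairs", "multi_value_cells", "constant_columns",
                 "duplicate_gene_mapping"),
    seed=3,
)


@pytest.fixture
def fixture_paths(tmp_path):
    return write_fixture(SPEC, tmp_path)


def load_bundle(series_path, platform_path):
    bundle = parse_series_matrix(series_path)
    bundle.features = parse_platform_table(platform_path)
    return bundle


def run_session(bundle, outdir):
    """A six-operation session ending in TSV exports."""
    session = Session(bundle, outdir)
    session.apply("split_key_value", "clinical", column="characteristics_ch1",
                  pattern={"text": ":", "mode": "literal"})
    session.apply("drop_by_preset", "clinical", presets=["same_value"])
    session.apply("attach_feature_ids", "assay",
                  target_id_column="GENE_SYMBOL", policy="drop")
    session.apply("summarize", "assay", stat="median")
    session.apply("transpose", "assay")
    session.apply("merge_tables", "merged", kind="inner", key="geo_accession")
    session.export("clinical", "tsv", "clinical.tsv")
    session.export("merged", "tsv", "merged.tsv")
    return session


def sha(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class TestSerialization:
    def test_empty_recipe_round_trips(self):
        r = Recipe()
        assert len(parse_recipe(serialize_recipe(r))) == 0

    def test_events_preserved_in_order(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        session = run_session(load_bundle(sp, pp), tmp_path / "out")
        again = parse_recipe(serialize_recipe(session.recipe))
        assert [e.op for e in again.events] == [e.op for e in session.recipe.events]
        assert [e.params for e in again.events] == [e.params for e in session.recipe.events]

    def test_serialization_is_canonical(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        session = run_session(load_bundle(sp, pp), tmp_path / "out")
        text = serialize_recipe(session.recipe)
        assert text == serialize_recipe(parse_recipe(text))

    def test_every_operation_appends_exactly_one_event(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        session = run_session(load_bundle(sp, pp), tmp_path / "out")
        assert len(session.recipe) == 8  # 6 ops + 2 exports


class TestReplay:
    def test_replay_reproduces_exports_byte_identically(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        session = run_session(load_bundle(sp, pp), tmp_path / "out1")
        recipe = parse_recipe(serialize_recipe(session.recipe))
        replay(recipe, load_bundle(sp, pp), tmp_path / "out2")
        for name in ("clinical.tsv", "merged.tsv"):
            assert sha(tmp_path / "out1" / name) == sha(tmp_path / "out2" / name)

    def test_replay_twice_is_deterministic(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        session = run_session(load_bundle(sp, pp), tmp_path / "o1")
        for d in ("r1", "r2"):
            replay(session.recipe, load_bundle(sp, pp), tmp_path / d)
        for name in ("clinical.tsv", "merged.tsv"):
            assert sha(tmp_path / "r1" / name) == sha(tmp_path / "r2" / name)

    def test_digest_mismatch_without_override_fails(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        session = run_session(load_bundle(sp, pp), tmp_path / "out")
        other_spec = PathologySpec(
            n_samples=6, pathologies=SPEC.pathologies, seed=99)
        osp, opp, _ = write_fixture(other_spec, tmp_path / "other")
        with pytest.raises(ReplayError, match="digest"):
            replay(session.recipe, load_bundle(osp, opp), tmp_path / "x")

    def test_override_fails_at_first_inapplicable_event(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        session = run_session(load_bundle(sp, pp), tmp_path / "out")
        mutated_spec = PathologySpec(
            n_samples=6, n_features=12,
            pathologies=("constant_columns", "duplicate_gene_mapping"), seed=3)
        msp, mpp, _ = write_fixture(mutated_spec, tmp_path / "mut")
        with pytest.raises(ReplayError, match=r"event 0"):
            replay(session.recipe, load_bundle(msp, mpp), tmp_path / "y",
                   override_digest=True)

    def test_empty_recipe_replay_is_identity(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        bundle = load_bundle(sp, pp)
        recipe = Recipe(input_digest=bundle_digest(bundle))
        session = replay(recipe, bundle)
        assert session.bundle.clinical.equals(bundle.clinical)

    def test_digest_depends_on_content(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        b = load_bundle(sp, pp)
        d1 = bundle_digest(b)
        b2 = load_bundle(sp, pp)
        b2.metadata["title"] = "changed"
        assert d1 != bundle_digest(b2)
        assert d1 == bundle_digest(load_bundle(sp, pp))


class TestGenerateScript:
    def test_one_commented_call_per_event(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        session = run_session(load_bundle(sp, pp), tmp_path / "out")
        script = generate_script(session.recipe)
        for event in session.recipe.events:
            assert script.count(f"# parameters:") == len(session.recipe.events)
            break
        assert script.count("tidy_ops.split_key_value") == 1
        assert script.count("export_io.write_table") == 2
        # parameters quoted verbatim in comments
        assert '"stat": "median"' in script

    def test_script_outputs_match_replay(self, fixture_paths, tmp_path):
        sp, pp, _ = fixture_paths
        session = run_session(load_bundle(sp, pp), tmp_path / "out1")
        script_path = tmp_path / "tidy_steps.py"
        script_path.write_text(generate_script(session.recipe))
        subprocess.run(
            [sys.executable, str(script_path), str(sp), str(pp),
             str(tmp_path / "out3")],
            check=True, capture_output=True,
        )
        for name in ("clinical.tsv", "merged.tsv"):
            assert sha(tmp_path / "out1" / name) == sha(tmp_path / "out3" / name)
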