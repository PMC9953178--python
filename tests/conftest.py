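"""Shared fixtures: synthetic worlds and pipeline configs."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from slanglex.pipeline import PipelineConfig
from slanglex.worlds import World, WorldSpec, build_world, make_world

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_world() -> World:
    """The default synthetic world: 5 index terms, 30 planted, 200 distractors."""
    return make_world(WorldSpec())


@pytest.fixture(scope="session")
def default_world_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("world") / "default"
    build_world(WorldSpec(), out)
    return out


@pytest.fixture(scope="session")
def fp_world_dir(tmp_path_factory) -> Path:
    """A world whose distractors carry a 0.2 search false-positive rate."""
    out = tmp_path_factory.mktemp("world") / "fp"
    build_world(WorldSpec(search_false_positive_rate=0.2, rng_seed=23), out)
    return out


def pipeline_config(world_dir: Path, output_dir: Path, **overrides) -> PipelineConfig:
    base = dict(
        seed_lexicon_path=world_dir / "seed_lexicon.tsv",
        controlled_list_path=world_dir / "controlled_substances.txt",
        hit_counts_path=world_dir / "hit_counts.tsv",
        labels_path=world_dir / "truth_labels.csv",
        world_path=world_dir,
        output_dir=output_dir,
        n_iterations=50,
        rng_seed=7,
    )
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture()
def make_config(tmp_path):
    def _make(world_dir: Path, name: str = "run", **overrides) -> PipelineConfig:
        return pipeline_config(world_dir, tmp_path / name, **overrides)

    return _make
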