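import numpy as np
import pytest

from comotif.motifs import PWM, Background, LogOddsMatrix
from comotif.pipeline import PipelineConfig, run_pipeline
from comotif.simulate import default_design, generate_compendium


def random_pwm(rng: np.random.Generator, width: int, motif_id: str = "m",
               informative: bool = False) -> PWM:
    """Random PWM; with ``informative`` each column has a dominant base."""
    if informative:
        probs = np.empty((4, width))
        for i in range(width):
            dom = int(rng.integers(4))
            p_dom = float(rng.uniform(0.85, 0.97))
            rest = rng.dirichlet([1.0, 1.0, 1.0]) * (1 - p_dom)
            col = np.empty(4)
            col[dom] = p_dom
            col[[b for b in range(4) if b != dom]] = rest
            probs[:, i] = col / col.sum()
    else:
        probs = rng.dirichlet([1.0] * 4, size=width).T
    return PWM(motif_id=motif_id, name=motif_id, source="synthetic", probs=probs)


def brute_force_tails(lom: LogOddsMatrix, bg: Background):
    """Exact tail probabilities by enumerating all 4^width words.

    Returns (achievable scores ascending, tail probability P(score >= s) for
    each). Independent of the dynamic-programming implementation.
    """
    w = lom.width
    grids = np.indices((4,) * w).reshape(w, -1)
    scores = lom.scores[grids, np.arange(w)[:, None]].sum(axis=0)
    probs = bg.freqs[grids].prod(axis=0)
    uniq = np.unique(scores)
    tails = np.array([probs[scores >= s].sum() for s in uniq])
    return uniq, tails


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_compendium(tmp_path_factory):
    """The seed-42 synthetic compendium written once per session."""
    out = tmp_path_factory.mktemp("compendium42")
    design = default_design(seed=42)
    paths = generate_compendium(design, out)
    return {"design": design, "paths": paths}


def _run_default_pipeline(paths, out_dir):
    config = PipelineConfig(
        genome=str(paths["genome"]),
        peaks_dir=str(paths["peaks_dir"]),
        metadata=str(paths["metadata"]),
        motifs=str(paths["motifs"]),
        canonical_map=str(paths["canonical_map"]),
        out_dir=str(out_dir),
        seed=42,
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def default_run(default_compendium, tmp_path_factory):
    """One full pipeline run on the default compendium (seed 42)."""
    out = tmp_path_factory.mktemp("run42")
    result = _run_default_pipeline(default_compendium["paths"], out)
    return {"result": result, "out_dir": out, **default_compendium}


@pytest.fixture(scope="session")
def repeat_run(default_compendium, tmp_path_factory):
    """A second, independent pipeline run for determinism checks."""
    out = tmp_path_factory.mktemp("run42_repeat")
    result = _run_default_pipeline(default_compendium["paths"], out)
    return {"result": result, "out_dir": out}
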