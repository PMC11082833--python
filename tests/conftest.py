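import numpy as np
import pytest

from ptrburst.pipeline import PipelineConfig, SimulateConfig, analyze, simulate_cohort
from ptrburst.preprocess import PreprocConfig, preprocess_datasets
from ptrburst.synthetic import BlockDesign, BurstSpec, RegionSpec, generate_dataset


def short_design(n_blocks: int = 10) -> BlockDesign:
    """Compact task/rest block design used for desk-scale fixtures: no
    instruction screen, 8 s task, 12 s rest, PTR window 0-7 s post-task."""
    return BlockDesign(
        instruction_dur=0.0, task_dur=8.0, rest_dur=12.0,
        n_blocks=n_blocks, ptr_window=(0.0, 7.0),
    )


def bursty_region(
    name: str,
    carrier: float,
    amplitude: float = 3.0,
    rate_ptr: float = 0.6,
    rate_task: float = 0.05,
    rate_rest: float = 0.05,
) -> RegionSpec:
    return RegionSpec(
        region_name=name,
        burst=BurstSpec(carrier, amplitude=amplitude, mean_duration=0.3,
                        duration_dispersion=0.05),
        rate_task=rate_task,
        rate_ptr=rate_ptr,
        rate_rest=rate_rest,
    )


@pytest.fixture(scope="session")
def analyzed_small():
    """Six-region, two-participant n-back style cohort run through the full
    in-memory pipeline (simulate at 600 Hz -> bandpass -> 100 Hz -> HMMs ->
    clustering -> PTR identification -> metrics)."""
    cfg = PipelineConfig(
        simulate=SimulateConfig(
            n_regions=6, n_participants=2, design="nback", n_blocks=4, fs=600.0
        ),
        n_restarts=2,
        max_iter=30,
    )
    datasets = simulate_cohort(cfg, seed=7)
    series = preprocess_datasets(
        datasets, PreprocConfig(band=cfg.band, target_fs=cfg.target_fs)
    )
    result = analyze(series, datasets[0].design, cfg, seed=7)
    return {"config": cfg, "datasets": datasets, "series": series, "result": result}


@pytest.fixture(scope="session")
def burst_recovery():
    """Twenty-region burst-recovery fixture: alternating 10 Hz (alpha) and
    20 Hz (beta) carriers, amplitude 3x background, mean duration 0.30 s,
    burst rate elevated in the post-task window; fixed seed.  Simulated
    directly at the 100 Hz analysis rate and analysed with the full
    pipeline."""
    design = short_design(n_blocks=10)
    regions = [
        bursty_region(f"r{i:02d}", 10.0 if i % 2 == 0 else 20.0)
        for i in range(20)
    ]
    ds = generate_dataset(regions, design, fs=100.0, participant_id="p00", seed=42)
    series = preprocess_datasets(
        [ds], PreprocConfig(band=(1.0, 45.0), target_fs=100.0)
    )
    cfg = PipelineConfig(band=(1.0, 45.0), n_restarts=3, max_iter=60)
    result = analyze(series, design, cfg, seed=42)
    return {"dataset": ds, "series": series, "result": result, "design": design}


def random_model(rng: np.random.Generator, K: int, d: int):
    """Random valid TdeHmmModel for oracle tests."""
    from ptrburst.hmm import TdeHmmModel

    covs = np.empty((K, d, d))
    for k in range(K):
        A = rng.standard_normal((d, d))
        covs[k] = A @ A.T + d * np.eye(d)
    trans = rng.dirichlet(np.ones(K) * 2.0, size=K)
    init = rng.dirichlet(np.ones(K))
    return TdeHmmModel(K=K, transition=trans, initial=init, covariances=covs)
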