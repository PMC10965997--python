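import numpy as np
import pandas as pd
import pytest

from domchemo.io import Dataset, SampleSpec
from domchemo.qc import (
    apply_intensity_floor,
    drop_invalid_formulae,
    remove_blank_and_contaminant_peaks,
    replicate_presence_filter,
)


def make_dataset(intensities: dict, samples: list[SampleSpec], normalized: bool = False) -> Dataset:
    """Assemble a Dataset from {formula: [per-sample intensities]}."""
    idx = pd.Index(list(intensities), name="formula")
    mat = pd.DataFrame(
        np.array(list(intensities.values()), dtype=float),
        index=idx,
        columns=[s.sample_id for s in samples],
    )
    return Dataset(intensities=mat, samples=samples, normalized=normalized)


def triplicate_specs(lake="alpine", treatment="control", timepoints=(0.0,), prefix=None):
    """SampleSpec triplicates for each timepoint of one (lake, treatment)."""
    prefix = prefix or f"{lake}_{treatment}"
    return [
        SampleSpec(
            sample_id=f"{prefix}_t{int(tp)}_r{rep}",
            lake=lake,
            treatment=treatment,
            timepoint_h=tp,
            replicate=rep,
        )
        for tp in timepoints
        for rep in (1, 2, 3)
    ]


@pytest.fixture(scope="session")
def sim_experiment():
    """One shared small synthetic experiment (module-expensive to build)."""
    from domchemo.simulate import SimConfig, generate_experiment

    cfg = SimConfig(n_core_formulae=500, noise_cv=0.05, seed=42)
    d, truth = generate_experiment(cfg)
    return cfg, d, truth


@pytest.fixture(scope="session")
def sim_filtered(sim_experiment):
    """The shared experiment after the pre-normalization QC stages."""
    _, d, _ = sim_experiment
    d = drop_invalid_formulae(d)
    d = remove_blank_and_contaminant_peaks(d)
    d = apply_intensity_floor(d)
    return replicate_presence_filter(d)
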