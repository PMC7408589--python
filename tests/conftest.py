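import pytest

from radassay import CellCycleTruth, SurvivalTruth, ViabilityTruth

BASELINE_FRACTIONS = {"subG1": 0.03, "G1": 0.34, "S": 0.25, "G2": 0.36, "polyploid": 0.02}


@pytest.fixture
def baseline_fractions():
    return dict(BASELINE_FRACTIONS)


@pytest.fixture
def cellcycle_truth(baseline_fractions):
    return CellCycleTruth(fractions=baseline_fractions)


@pytest.fixture
def survival_truth():
    return SurvivalTruth.with_target_colonies(
        d0=1.45,
        n_extrap=1.327,
        plating_efficiency=0.64,
        doses=(0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
        replicates=18,  # 6 dishes x 3 pooled experiments
        target_colonies=50.0,
    )


@pytest.fixture
def viability_truth():
    return ViabilityTruth(
        dose_to_viability={
            0.0: 100.0,
            1.0: 92.0,
            2.0: 75.0,
            4.0: 55.0,
            6.0: 35.0,
            8.0: 24.0,
            10.0: 16.0,
            12.0: 12.0,
        },
        od_untreated_mean=0.90,
        od_blank_mean=0.08,
        noise_sd=0.01,
        floor_pct=20.0,
    )
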