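import numpy as np
import pytest

from polyorigins import (
    LocusAlignment,
    PolyploidScenario,
    PriorSet,
    ScenarioParameters,
    Sequence,
    StudyConfig,
    generate_study,
)


def make_alignment(locus_id, rows):
    """rows: list of (sample_id, hap_index, residue string)."""
    return LocusAlignment(
        locus_id, [(sid, hap, Sequence(f"{sid}|hap{hap}", res)) for sid, hap, res in rows]
    )


def random_alignment(rng, n_samples=3, length=40, ploidies=None, locus_id="toy"):
    """Random nucleotide alignment with occasional missing cells."""
    bases = np.array([b"A", b"C", b"G", b"T", b"N", b"-"])
    probs = [0.28, 0.28, 0.18, 0.18, 0.05, 0.03]
    rows = []
    ploidies = ploidies or [2] * n_samples
    for s, ploidy in enumerate(ploidies):
        for h in range(2 * ploidy // 2 if ploidy == 2 else 4):
            res = rng.choice(bases, size=length, p=probs).tobytes().decode()
            rows.append((f"s{s}", h, res))
    return make_alignment(locus_id, rows)


@pytest.fixture(scope="session")
def tiny_study():
    """Clean miniature study: no missing data, no phase error."""
    config = StudyConfig(
        n_loci=6,
        n_diploid=6,
        n_tetraploid=4,
        locus_length_mean=500,
        locus_length_sd=60,
        locus_length_min=300,
        missing_rate=0.0,
        phase_error_rate=0.0,
        seed=1234,
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def degraded_study():
    """Miniature study with the emulated 2.7% missing-cell rate."""
    config = StudyConfig(
        n_loci=6,
        n_diploid=6,
        n_tetraploid=4,
        locus_length_mean=500,
        locus_length_sd=60,
        locus_length_min=300,
        missing_rate=0.027,
        phase_error_rate=0.0,
        seed=77,
    )
    return generate_study(config)


# --- desk-scale self-consistency experiment design -------------------------
# Narrow priors in which the six speciation models are mutually identifiable
# (under the full-width migration priors, migration erases the formation
# signal over most of prior mass), plus an identifiable generating point.


@pytest.fixture(scope="session")
def scaled_priors():
    return PriorSet(
        N_dip=(5e4, 5e5),
        N_ext=(5e4, 5e5),
        N_tet=(5e4, 5e5),
        N_anc=(5e4, 5e5),
        T_split=(1e6, 8e6),
        T_WGD=(1e4, 1e6),
        m_dip_to_A=(0, 5e-6),
        m_dip_to_B=(0, 5e-6),
        m_A_to_dip=(0, 5e-6),
        m_B_to_dip=(0, 5e-6),
    )


@pytest.fixture(scope="session")
def scaled_true_params():
    return ScenarioParameters(
        N_dip=2e5,
        N_ext=2e5,
        N_tet=2e5,
        N_anc=2e5,
        T_split=4e6,
        T_WGD=3e5,
        m_dip_to_A=1.5e-6,
        m_dip_to_B=1.5e-6,
    )


@pytest.fixture(scope="session")
def recovery_scenario():
    return PolyploidScenario("autopolyploid", "tetrasomic", "unidirectional_dip_to_AB")
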