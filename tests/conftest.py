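import numpy as np
import pytest

from sfxtriage.synthmaker import SynthConfig, generate_stack


@pytest.fixture(scope="session")
def small_stack(tmp_path_factory):
    """3 synthetic files x 20 events with default artefact conditions."""
    cfg = SynthConfig(n_frames=60, n_files=3, seed=5)
    return generate_stack(cfg, tmp_path_factory.mktemp("small_stack"))


@pytest.fixture(scope="session")
def clean_stack(tmp_path_factory):
    """Spot-free, low-noise stack whose inflection signatures cluster
    tightly: the regime the profile-fit auto-labeller is designed for."""
    cfg = SynthConfig(n_frames=40, n_spots=0, noise_sigma=0.02,
                      artefact_offset=15.0, seed=3)
    return generate_stack(cfg, tmp_path_factory.mktemp("clean_stack"))


def make_quartic_profile(r1: float, r2: float, length: int = 101,
                         lead: float = 1.0) -> np.ndarray:
    """Quartic whose second derivative vanishes exactly at r1 and r2.

    d2(x) = 12*lead*(x - r1)*(x - r2) integrates to
    lead*(x^4 - 2(r1+r2)x^3 + 6 r1 r2 x^2); the best-fit line is then
    subtracted (inflections unchanged) so the profile's range reflects
    its curvature structure, like a ring bump crossing the ROI, rather
    than the raw quartic's end-point growth.
    """
    x = np.arange(length, dtype=float)
    p = lead * (x ** 4 - 2.0 * (r1 + r2) * x ** 3 + 6.0 * r1 * r2 * x ** 2)
    lin = np.polynomial.polynomial.polyfit(x, p, 1)
    return p - np.polynomial.polynomial.polyval(x, lin)


def draw_quartic_inflections(rng: np.random.Generator) -> tuple[float, float]:
    """Curvature roots of the synthetic quartic family: straddling the
    profile midpoint, >= 20 rows apart, >= 25 rows from either edge."""
    return float(rng.uniform(25, 40)), float(rng.uniform(60, 75))
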