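import numpy as np
import pandas as pd
import pytest

from twinlink.syntwin import generate_latent_scores, two_trait_config
from twinlink.twinmodel import PairData


def latent_pair_data(seed=0, n_mz=4000, n_dz=4000, **kwargs) -> PairData:
    """Two-trait latent-level pair data under a known ACE truth."""
    cfg = two_trait_config(n_mz=n_mz, n_dz=n_dz, seed=seed, **kwargs)
    return PairData.from_latents(generate_latent_scores(cfg), "trait1", "trait2")


def ace_moments(a2, c2, rA=0.0, rC=0.0, rE=0.0):
    """Population mean/covariance of a bivariate ACE process with unit
    trait variances; the independent closed-form route."""
    a2 = np.asarray(a2, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    e2 = 1.0 - a2 - c2
    h = np.sqrt(a2)
    c = np.sqrt(c2)
    e = np.sqrt(e2)
    A = np.array([[a2[0], h[0] * h[1] * rA], [h[0] * h[1] * rA, a2[1]]])
    C = np.array([[c2[0], c[0] * c[1] * rC], [c[0] * c[1] * rC, c2[1]]])
    E = np.array([[e2[0], e[0] * e[1] * rE], [e[0] * e[1] * rE, e2[1]]])
    T = A + C + E
    S = {}
    for g, w in (("MZ", 1.0), ("DZ", 0.5)):
        B = w * A + C
        S[g] = np.block([[T, B], [B, T]])
    return np.zeros(4), S["MZ"], S["DZ"]


@pytest.fixture(scope="session")
def moment_data():
    """Exact-moment pair data at an interior bivariate ACE truth."""
    mu, Smz, Sdz = ace_moments(a2=(0.5, 0.5), c2=(0.2, 0.2), rA=0.3, rC=0.1, rE=0.1)
    return PairData.from_moments(mu, Smz, mu, Sdz, n=5000)


@pytest.fixture(scope="session")
def simulated_ae_data():
    """One simulated cohort at the canonical AE truth (a2 0.6/0.5, rA 0.5,
    rE 0.2), 4000 MZ + 4000 DZ pairs."""
    return latent_pair_data(seed=20, a2=(0.6, 0.5), rA=0.5, rE=0.2)


def ten_pair_filter_fixture() -> pd.DataFrame:
    """Hand-built scored table: 10 pairs of which 2 have a screen-failing
    twin, 1 is a singleton and 1 has undetermined zygosity -> 6 survive."""
    rows = []
    for pid in range(1, 11):
        for twin in (1, 2):
            rows.append(
                {
                    "pair_id": pid,
                    "twin": twin,
                    "zygosity": "MZ" if pid % 2 else "DZ_ss",
                    "sex": "F",
                    "birth_year": 2000,
                    "screen_excluded": False,
                    "absent": False,
                    "synaesthesia_score": 1.0,
                    "oc_score": 3.0,
                }
            )
    df = pd.DataFrame(rows)
    idx = df.set_index(["pair_id", "twin"]).index

    def mark(pid, twin, **kv):
        for k, v in kv.items():
            df.loc[idx.get_loc((pid, twin)), k] = v

    # pairs 1 and 2: one twin fails the screen rule
    for pid in (1, 2):
        mark(pid, 1, screen_excluded=True, synaesthesia_score=np.nan)
    # pair 3: twin 2 did not participate
    mark(3, 2, absent=True, synaesthesia_score=np.nan, oc_score=np.nan)
    # pair 4: undetermined zygosity
    for twin in (1, 2):
        mark(4, twin, zygosity="undetermined")
    return df
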