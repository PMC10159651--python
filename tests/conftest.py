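import io

import numpy as np
import pytest

import profhmm as P


@pytest.fixture(scope="session")
def amino():
    return P.Alphabet.amino()


@pytest.fixture(scope="session")
def background():
    return P.Background.amino()


@pytest.fixture(scope="session")
def small_hmm():
    """A fixed random 5-node model used across file/DP tests."""
    return P.random_hmm(5, seed=3)


@pytest.fixture(scope="session")
def calibrated_hmm():
    """A mid-sized calibrated model (calibration is the slow step, so
    it is shared session-wide; tests must not mutate it)."""
    h = P.random_hmm(20, seed=11, name="cal20")
    P.calibrate(h, seed=42)
    return h


def serialize_tophits(results) -> str:
    """Canonical text form used for result-identity comparisons."""
    buf = io.StringIO()
    P.write_tblout(list(results), buf)
    return buf.getvalue()


def roundtrip_text(hmms) -> str:
    buf = io.StringIO()
    P.write_hmm_file(hmms, buf, include_date=False)
    return buf.getvalue()
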