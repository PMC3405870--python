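import numpy as np
import pytest

from ckrdiv.substitution import SubstitutionModel


@pytest.fixture(scope="session")
def blosum():
    """BLOSUM62 model with lambda_u solved once for the whole session."""
    return SubstitutionModel.blosum62().with_lambda()


@pytest.fixture(scope="session")
def toy2():
    """Two-letter model whose lambda_u has the closed form ln((1+sqrt(5))/2)."""
    model = SubstitutionModel(
        alphabet="AB",
        scores=np.array([[1.0, -2.0], [-2.0, 1.0]]),
        background=np.array([0.5, 0.5]),
    )
    return model.with_lambda()


@pytest.fixture(scope="session")
def exact_logodds():
    """3-letter matrix that is an exact log-odds of a joint distribution.

    q = 0.7*diag(P) + 0.3*P P^T has marginals P, so s = ln(q/PP^T)/lambda0
    solves the ungapped constraint exactly at lambda0 and makes the
    pseudocount fixed point f = P -> g = P exact.
    """
    lam0 = 0.4
    p = np.array([0.3, 0.2, 0.5])
    q = 0.7 * np.diag(p) + 0.3 * np.outer(p, p)
    s = np.log(q / np.outer(p, p)) / lam0
    model = SubstitutionModel(alphabet="XYZ", scores=s, background=p)
    return model, lam0
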