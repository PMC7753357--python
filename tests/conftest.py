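import numpy as np
import pandas as pd
import pytest

from teicopk.cohort import make_cohort
from teicopk.covariates import ThetaSet, individual_cl, individual_vd
from teicopk.pk_core import DoseEvent, PKParameters, Regimen, conc_profile

COHORT_SEED = 1234  # one fixed draw of the 5000-child virtual population


@pytest.fixture(scope="session")
def cohort5000():
    """The study-condition virtual cohort shared across simulation tests."""
    return make_cohort(5000, seed=COHORT_SEED)


def build_event_df(subjects, theta: ThetaSet | None = None):
    """Assemble a NONMEM-style event DataFrame from a compact description.

    ``subjects`` maps id -> dict(wt, scr, doses=[(time, amt, dur)],
    obs=[(time, dv)]).
    """
    rows = []
    for sid, d in subjects.items():
        base = dict(WT=d["wt"], SCR=d["scr"], AGE=d.get("age", 4.0), SEX=d.get("sex", 1))
        for t, a, dur in d["doses"]:
            rows.append(
                dict(ID=sid, TIME=t, AMT=a, RATE=a / dur, DV=np.nan, EVID=1, MDV=1,
                     LLOQFL=0, **base)
            )
        for t, y in d["obs"]:
            rows.append(
                dict(ID=sid, TIME=t, AMT=np.nan, RATE=np.nan, DV=y, EVID=0, MDV=0,
                     LLOQFL=0, **base)
            )
    return pd.DataFrame(rows)


def model_observations(wt, scr, eta, doses, times, sigma=0.0, eps=None, theta=None):
    """Noiseless (or log-perturbed) model predictions for a toy subject."""
    theta = theta or ThetaSet()
    cl = individual_cl(wt, scr, theta, eta[0])
    v = individual_vd(wt, theta, eta[1])
    reg = Regimen(tuple(DoseEvent(t, a, dur) for t, a, dur in doses))
    f = conc_profile(PKParameters(cl, v), reg, times)
    if eps is not None:
        f = f * np.exp(sigma * np.asarray(eps))
    return list(zip(times, [float(x) for x in f]))
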