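import warnings

import numpy as np
import pytest

from koaprog.cohort import CohortTable
from koaprog.labeling import ProgressionLabeler
from koaprog.preprocess import CohortPreprocessor
from koaprog.synthdata import CohortSpec, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
try:  # sklearn's convergence warning is noise at desk-scale iteration caps
    from sklearn.exceptions import ConvergenceWarning

    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:
    pass


SMALL_ALLOCATION = {"clinical": 60, "imaging": 40}


@pytest.fixture(scope="session")
def small_cohort():
    """400 subjects, 100 features (20 planted), noiseless trajectories."""
    spec = CohortSpec(
        n_subjects=400,
        category_allocation=dict(SMALL_ALLOCATION),
        n_informative=20,
        missing_profile={0.30: 4, 0.05: 6},
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def balanced_xy(small_cohort):
    """Balanced, preprocessed (X, y, truth) from the small cohort."""
    lab = ProgressionLabeler(k=2, random_state=5).fit(small_cohort.trajectories)
    ids = lab.balanced_ids_
    y = lab.classes_.loc[ids].to_numpy()
    table = small_cohort.features
    bal = CohortTable(
        data=table.data.loc[ids], kinds=table.kinds, categories=table.categories
    )
    prep = CohortPreprocessor().fit(bal)
    X = prep.transform(bal).data
    return X, y, small_cohort.truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
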