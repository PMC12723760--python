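"""Latent class mixed models for heterogeneous cognitive decline.

Tools for identifying latent classes of Preclinical Alzheimer Cognitive
Composite (PACC) trajectories in cognitively unimpaired, biomarker-phenotyped
cohorts such as A4/LEARN: a synthetic cohort generator with known ground
truth, Box-Cox / natural-spline preprocessing, EM estimation of the latent
class mixed-effects model with a multinomial-logit membership submodel,
BIC/ICL model selection, cross-validated baseline-only class prediction,
class-specific clinical-trial power, and CART characterization of classes.
"""

from pacctraj.cohort import CohortData, read_cohort, write_cohort
from pacctraj.transforms import (
    BoxCoxTransform,
    SplineBasis,
    fit_boxcox,
    residualize_and_z,
    tau_composite,
)

__version__ = "0.1.0"

__all__ = [
    "CohortData",
    "read_cohort",
    "write_cohort",
    "BoxCoxTransform",
    "SplineBasis",
    "fit_boxcox",
    "residualize_and_z",
    "tau_composite",
    "__version__",
]
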