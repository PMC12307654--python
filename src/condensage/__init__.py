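"""condensage: quantitative analysis of aging biomolecular condensates.

A library for the measurements by which condensate aging is characterized:
passive particle-tracking microrheology (MSD, diffusive exponent, GSER
viscoelastic moduli, Maxwell crossover, material-state classification), FRAP
mobility analysis, enzyme and thioflavin-T kinetics, and condensate image
metrics — together with synthetic-data generators that provide every input
class with known ground truth.
"""

from . import frap, imaging, kinetics, microrheology, synthetic, tracking
from .frap import (
    FrapFit,
    FrapRecord,
    analyze_frap,
    apparent_diffusion,
    correct_and_normalize,
    fit_recovery,
    immobile_fraction,
    immobile_ratio,
    relative_immobile,
)
from .imaging import (
    CondensateImage,
    SegmentationResult,
    enrichment_index,
    line_profile,
    relative_count,
    segment_condensates,
)
from .kinetics import (
    KineticsDataset,
    MentenFit,
    SigmoidFit,
    ThTSeries,
    absorbance_to_conc,
    fit_menten,
    fit_sigmoid,
    initial_rate,
    relative_rate,
)
from .microrheology import (
    GserParams,
    MaterialState,
    ModuliCurve,
    MsdCurve,
    PowerLawFit,
    classify_timecourse,
    compute_msd,
    find_crossover,
    fit_powerlaw,
    gser_moduli,
)
from .synthetic import (
    FrameStack,
    FrapGroundTruth,
    MotionModel,
    SimulationConfig,
    TrajectoryEnsemble,
    render_condensate_image,
    render_frames,
    simulate_frap,
    simulate_kinetics,
    simulate_tht,
    simulate_trajectories,
)
from .tracking import LinkingParams, Localization, detect_spots, link_trajectories

__version__ = "0.1.0"
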