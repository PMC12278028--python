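"""neuromap: a semantic hypersphere map of EEG.

10-second EEG spectrogram segments are embedded onto a unit 128-D
hypersphere by triplet-loss metric learning.  The resulting map supports
class geometry analysis (medians, cosine distances, MDS), cross-validated
classification, burst-suppression quantification, and outcome
prognostication from long-term trajectory dynamics.
"""

from neuromap.io import Recording, read_edf, write_edf
from neuromap.preprocess import (
    BipolarMontage,
    DEFAULT_MONTAGE,
    Segment,
    SpectroSegment,
    filter_standard,
    multitaper_spectrogram,
    rereference_bipolar,
    resample,
    segment_recording,
)
from neuromap.synthetic import (
    CLASSES,
    CohortSpec,
    generate_bs_signal,
    generate_class_segment,
    generate_cohort,
)
from neuromap.embedding import (
    Embedding,
    TrainConfig,
    Triplet,
    build_model,
    embed,
    sample_triplet,
    train,
    triplet_loss,
)
from neuromap.mapgeom import (
    class_medians,
    classify_cv,
    cosine_distance,
    mds_project,
    median_distance_matrix,
    roc_pr_one_vs_all,
    youden_point,
)
from neuromap.grid import SphereGrid, nearest_coordinate, relax, sample_sphere, used_coordinates
from neuromap.bsr import BsrParams, BsrResult, bsr, bsr_category, detect_suppressions
from neuromap.trajectory import (
    Trajectory,
    SymbolicSequence,
    distance_to_healthy,
    dynamics_features,
    group_occupancy_compare,
    lda_search,
    occupancy,
    outcome_classify,
    project_trajectory,
    symbolize,
    transition_entropy,
)

__version__ = "0.1.0"
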