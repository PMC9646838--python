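"""hipomap: fixed-size representation maps for whole-slide image analysis.

Converts a slide — an arbitrary-size bag of patches — into one K×(H·W)
matrix by ranking patches with a scoring CNN, weighting the exposed
activation maps of each top patch by the rectified summed gradients of the
class objective, and stacking the sorted flattened feature maps.  Small CNNs
then perform slide-level classification, Cox survival analysis and survival
regression on the maps.
"""

from .cohort import (Patch, Slide, SyntheticCohortSpec, TextureParams,
                     generate_cohort, generate_survival, read_slide_dir,
                     write_cohort)
from .core import (DEFAULT_K, ClassFeatureMap, HipoMap, ImportanceVector,
                   PatchRepresentation, build_hipomap, class_feature_map,
                   compute_importance, hipomap_to_png, hipomap_to_tsv,
                   load_hipomap, patch_representation, rank_top_k,
                   save_hipomap, slide_to_hipomap)
from .manifest import (CohortManifest, load_config, read_manifest,
                       setup_logging, stratified_split, write_manifest)
from .preprocess import (ReferenceStats, TissueMask, color_normalize,
                         detect_tissue, extract_patches, reference_stats)
from .scoring import (ActivationBundle, PatchCNN, PatchScore,
                      activation_bundle, activation_bundles, score_patches,
                      train_patch_model)
from .tasks import (GI_SURVIVAL_EXAMPLE, SlideModel, SlideModelConfig,
                    SurvivalBatch, baseline_max, baseline_mean,
                    concordance_index, cox_npll, cox_npll_grad, evaluate,
                    train_slide_model)

__version__ = "0.1.0"

__all__ = [
    "Patch", "Slide", "SyntheticCohortSpec", "TextureParams",
    "generate_cohort", "generate_survival", "read_slide_dir", "write_cohort",
    "DEFAULT_K", "ClassFeatureMap", "HipoMap", "ImportanceVector",
    "PatchRepresentation", "build_hipomap", "class_feature_map",
    "compute_importance", "hipomap_to_png", "hipomap_to_tsv", "load_hipomap",
    "patch_representation", "rank_top_k", "save_hipomap", "slide_to_hipomap",
    "CohortManifest", "load_config", "read_manifest", "setup_logging",
    "stratified_split", "write_manifest",
    "ReferenceStats", "TissueMask", "color_normalize", "detect_tissue",
    "extract_patches", "reference_stats",
    "ActivationBundle", "PatchCNN", "PatchScore", "activation_bundle",
    "activation_bundles", "score_patches", "train_patch_model",
    "GI_SURVIVAL_EXAMPLE", "SlideModel", "SlideModelConfig", "SurvivalBatch",
    "baseline_max", "baseline_mean", "concordance_index", "cox_npll",
    "cox_npll_grad", "evaluate", "train_slide_model",
]
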