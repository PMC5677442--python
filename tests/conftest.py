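import numpy as np
import pytest

from moundscan import (
    SceneSpec,
    classify_cube,
    default_spectra,
    detect_mounds,
    extract_layers,
    generate_scene,
    match_detections,
    plan_mounds,
    render_templates,
    to_reflectance,
    train_classifier,
)
from moundscan.synthetic_scene import GRASS_NAME, SOIL_NAME

# Simulations are run at a reduced band count (24 instead of the sensor's
# 274) to keep the suite fast; the spectral windows that separate the
# materials are still sampled by several bands each.
N_BANDS = 24


@pytest.fixture(scope="session")
def library():
    return default_spectra(N_BANDS)


@pytest.fixture(scope="session")
def classifier(library):
    return train_classifier(library, seed=7)


@pytest.fixture(scope="session")
def templates():
    return render_templates()


@pytest.fixture(scope="session")
def scene_runner(library, classifier, templates):
    """Generate a scene, run the full pipeline, and evaluate against truth."""

    def run(
        seed,
        n_mounds,
        noise=0.01,
        blur=0.5,
        dist=0.0,
        rows=192,
        cols=192,
        want_layers=False,
    ):
        mounds = plan_mounds(rows, cols, n_mounds, seed=seed)
        spec = SceneSpec(
            rows=rows,
            cols=cols,
            n_bands=N_BANDS,
            mounds=mounds,
            noise_sd=noise,
            blur_sigma_px=blur,
            distortion_amp_px=dist,
            seed=seed,
        )
        cube, white, truth = generate_scene(spec, library)
        refl = to_reflectance(cube, white)
        labels = classify_cube(refl, classifier)
        label_match = float(np.mean(labels.labels == truth.material_map))
        soil, grass = extract_layers(labels, library, [SOIL_NAME, GRASS_NAME])
        detections, overlay = detect_mounds(soil, grass, templates)
        counts = match_detections(detections, truth)
        out = {
            "label_match": label_match,
            "counts": counts,
            "detections": detections,
            "truth": truth,
            "overlay": overlay,
        }
        if want_layers:
            out.update(soil=soil, grass=grass, labels=labels)
        return out

    return run


def disk_mask(radius: int, size: int) -> np.ndarray:
    c = (size - 1) / 2
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
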