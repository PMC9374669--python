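import numpy as np
import pytest

from polycap import evaluate, sim
from polycap.head import HeadConfig
from polycap.net import build_network, compact_spec
from polycap.synth import SynthConfig, generate_dataset
from polycap.train import TrainConfig, split_by_patient, train_detector

# Frozen desk-scale benchmark: >= 2000 frames at reduced resolution, fixed
# seed, scaled-down epochs.  Shared (session-scoped) between the training
# property tests and the acceptance suite so the run happens once.
BENCH_SEED = 7
BENCH_FRAME_SIZE = 64
BENCH_SYNTH = SynthConfig(
    n_patients=25, frames_per_patient=84, frame_size=BENCH_FRAME_SIZE,
    polyp_size_range=(40.0, 110.0), seed=BENCH_SEED,
)
BENCH_TRAIN = TrainConfig(epochs=30, seed=BENCH_SEED, patience=30, lr_decay=0.93)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def bench_dataset():
    return generate_dataset(BENCH_SYNTH)


@pytest.fixture(scope="session")
def bench_split(bench_dataset):
    return split_by_patient(bench_dataset, rng=np.random.default_rng(BENCH_SEED))


@pytest.fixture(scope="session")
def trained_detector(bench_split):
    """Detector trained on the frozen synthetic benchmark (runs once)."""
    head = HeadConfig().scaled(BENCH_FRAME_SIZE)
    network = build_network(compact_spec(BENCH_FRAME_SIZE), rng_seed=BENCH_SEED)
    network, history = train_detector(network, bench_split, BENCH_TRAIN, head=head)
    return network, history


@pytest.fixture(scope="session")
def bench_test_detections(trained_detector, bench_split):
    """(detections, ground truths) pairs on the held-out test patients."""
    network, _ = trained_detector
    head = HeadConfig(score_threshold=0.01).scaled(BENCH_FRAME_SIZE)
    return [(list(sim.detect(network, f, head)), f.boxes) for f in bench_split.test]


def ap_at(pairs, threshold):
    return evaluate.evaluate_detections(pairs, threshold).ap
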