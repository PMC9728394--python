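import numpy as np
import pytest

from asase.geometry import ReactiveGeometry
from asase.synthetic import PoseEnsembleSpec, generate_pose_ensemble


@pytest.fixture(scope="session")
def small_ensemble():
    """200 poses with 2 hydroxyls and a 30% reactive target, seed-fixed."""
    return generate_pose_ensemble(
        PoseEnsembleSpec(
            n_conformations=200, ligand_name="HQ", n_hydroxyls=2,
            fraction_reactive_target=0.3, seed=11,
        )
    )


def make_geometries(d1, a1, d2=2.0, reactive=None):
    """Build ReactiveGeometry records from plain arrays (test helper)."""
    d1 = np.atleast_1d(np.asarray(d1, dtype=float))
    a1 = np.atleast_1d(np.asarray(a1, dtype=float))
    d2 = np.broadcast_to(np.asarray(d2, dtype=float), d1.shape)
    if reactive is None:
        reactive = (d1 < 4.0) & (d2 < 4.0) & (80.0 < a1) & (a1 < 140.0)
    else:
        reactive = np.broadcast_to(np.asarray(reactive, dtype=bool), d1.shape)
    return [
        ReactiveGeometry(
            pose_id=i + 1, hydroxyl_serial=1, hydroxyl_name="O1",
            d1=float(a), d2=float(c), a1=float(b), reactive=bool(r),
        )
        for i, (a, b, c, r) in enumerate(zip(d1, a1, d2, reactive))
    ]
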