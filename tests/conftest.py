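"""Shared fixtures: the reference-donor pipeline run and the analytic
composite-cylinder solve, both session-scoped because they back several
independent checks."""

import numpy as np
import pytest
import trimesh


@pytest.fixture(scope="session")
def donor_report():
    """Full pipeline on the reference donor spine (seed 1)."""
    from spinefea import default_donor_spine, run_pipeline

    return run_pipeline(default_donor_spine(noise_seed=1))


@pytest.fixture(scope="session")
def oracle_check():
    """Composite-cylinder FE solve vs the equal-strain closed form."""
    from spinefea.validation import composite_cylinder_oracle

    return composite_cylinder_oracle()


@pytest.fixture()
def sliver_cylinder():
    """Capped cylinder triangulated with tall, thin lateral triangles
    (min angle ~7.5 deg): a deliberately degenerate remeshing input."""
    nth, nz, r, h = 48, 3, 20.0, 25.0
    theta = np.linspace(0, 2 * np.pi, nth, endpoint=False)
    zs = np.linspace(-h / 2, h / 2, nz + 1)
    verts = [(r * np.cos(t), r * np.sin(t), z) for z in zs for t in theta]
    faces = []
    for k in range(nz):
        for i in range(nth):
            a = k * nth + i
            b = k * nth + (i + 1) % nth
            c = (k + 1) * nth + i
            d = (k + 1) * nth + (i + 1) % nth
            faces += [(a, b, d), (a, d, c)]
    bot = len(verts)
    verts.append((0.0, 0.0, -h / 2))
    top = len(verts)
    verts.append((0.0, 0.0, h / 2))
    for i in range(nth):
        faces.append((bot, (i + 1) % nth, i))
        faces.append((top, nz * nth + i, nz * nth + (i + 1) % nth))
    return trimesh.Trimesh(
        vertices=np.asarray(verts, dtype=float), faces=np.asarray(faces), process=False
    )
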