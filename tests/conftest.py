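"""Shared fixtures: phantoms, coordinate fields, warps and pipeline outputs.

Everything is generated programmatically; the expensive artifacts (Laplace
solves on the default phantom, the end-to-end pipeline run) are
session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import unfoldcoords as uc
from unfoldcoords.core import UnfoldedSpaceSpec


@pytest.fixture(scope="session")
def phantom_bundle():
    """Default curled, digitated phantom with analytic truth."""
    lm, truth = uc.generate_phantom()
    return lm, truth


@pytest.fixture(scope="session")
def slab_bundle():
    """Flat-slab phantom (no curl, no digitations)."""
    params = uc.PhantomParams(curl_turns=0.0, n_digitations=0, digitation_amplitude=0.0)
    lm, truth = uc.generate_phantom(params)
    return lm, truth


@pytest.fixture(scope="session")
def template():
    return uc.generate_template()


@pytest.fixture(scope="session")
def fields(phantom_bundle):
    """Equivolumetric coordinate fields solved on the default phantom GM."""
    lm, _ = phantom_bundle
    return uc.compute_coord_fields(lm)


@pytest.fixture(scope="session")
def slab_fields(slab_bundle):
    lm, _ = slab_bundle
    return uc.compute_coord_fields(lm)


@pytest.fixture(scope="session")
def spec():
    return UnfoldedSpaceSpec()


@pytest.fixture(scope="session")
def warps_pair(phantom_bundle, fields, spec):
    lm, _ = phantom_bundle
    w_n2u = uc.build_native_to_unfolded(fields, lm, spec)
    w_u2n = uc.build_unfolded_to_native(fields, lm, spec)
    return w_n2u, w_u2n


@pytest.fixture(scope="session")
def unfoldiso_layers(warps_pair, spec):
    _, w_u2n = warps_pair
    return uc.build_layer_surfaces(w_u2n, "unfoldiso", spec)


@pytest.fixture(scope="session")
def schematic_atlas():
    return uc.make_schematic_atlas()


@pytest.fixture(scope="session")
def pipeline_results(tmp_path_factory, phantom_bundle, template):
    """Full pipeline (with template shape injection) on the default phantom."""
    lm, _ = phantom_bundle
    cfg = uc.PipelineConfig(
        subject_id="phantom",
        densities=("unfoldiso", "2mm"),
        out_dir=tmp_path_factory.mktemp("pipeline_out"),
    )
    return uc.run_pipeline(cfg, labelmap=lm, template=template)


def make_flat_grid_mesh(n=12, m=12, spacing=1.0):
    """Plain planar triangulated grid (z=0) used by morphometry oracles."""
    from unfoldcoords.surfaces import SurfaceMesh

    xs = np.arange(n) * spacing
    ys = np.arange(m) * spacing
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([XX.ravel(), YY.ravel(), np.zeros(n * m)])
    tris = []
    for i in range(n - 1):
        for j in range(m - 1):
            a = i * m + j
            tris.append([a, a + m, a + m + 1])
            tris.append([a, a + m + 1, a + 1])
    uv = np.column_stack([XX.ravel() / xs.max(), YY.ravel() / ys.max()])
    return SurfaceMesh(verts, np.array(tris), "native", "unfoldiso", "hipp",
                       "midthickness", uv=uv)
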