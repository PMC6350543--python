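"""Synthetic phantom generation: 2D photographs and 3D meshes.

Convenience namespace re-exporting the 2D scene renderer
(:mod:`lesionmetry.phantom2d`) and the 3D mesh phantoms
(:mod:`lesionmetry.phantom3d`).
"""

from .phantom2d import (  # noqa: F401
    PhantomSceneSpec,
    PhantomTruth,
    RulerSpec,
    ShapeSpec,
    SupportSpec,
    centered_shape,
    random_scene,
    regular_polygon_vertices,
    render_cylinder_phantom,
    render_flat_phantom,
    render_phantom,
    ruler_corner_chart_points,
)
from .phantom3d import (  # noqa: F401
    MeshPhantom,
    Surface3D,
    make_mesh_phantom,
    orbit_trajectory,
    render_mesh_views,
)
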