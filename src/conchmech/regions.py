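"""Region-label vocabulary shared by the surface generator, mesher and solver.

Surface (mid-surface) triangles carry exactly one label from
:data:`SURFACE_REGIONS`.  When a mid-surface is extruded into a volumetric
mesh, each triangle produces an *outer* boundary face (offset along the
outward normal) and an *inner* one; the two sides of a shell wall are wetted
by different media, so face labels are assigned per side via
:data:`OUTER_FACE_LABEL` / :data:`INNER_FACE_LABEL`.  Faces created along free
surface edges (aperture rim, foramen rim tunnels) are labelled ``edge_rim``.
"""

EXTERNAL_WALL = "external_wall"
BODY_CHAMBER_INTERIOR = "body_chamber_interior"
FINAL_SEPTUM_ADAPERTURAL = "final_septum_adapertural"
FINAL_SEPTUM_ADAPICAL = "final_septum_adapical"
SEPTUM_INTERNAL = "septum_internal"
SUTURE_BAND = "suture_band"
FORAMEN_RIM = "foramen_rim"
VALIDATION = "validation"
WALL_INTERIOR = "wall_interior"
EDGE_RIM = "edge_rim"

#: labels permitted on mid-surface triangles (a partition)
SURFACE_REGIONS = (
    EXTERNAL_WALL,
    BODY_CHAMBER_INTERIOR,
    FINAL_SEPTUM_ADAPERTURAL,
    SEPTUM_INTERNAL,
    SUTURE_BAND,
    FORAMEN_RIM,
    VALIDATION,
)

#: the three wetted regions of the hydrostatic load case
HYDROSTATIC_REGIONS = (
    EXTERNAL_WALL,
    BODY_CHAMBER_INTERIOR,
    FINAL_SEPTUM_ADAPERTURAL,
)

# Extrusion side rules.  A body-chamber wall triangle is external shell on its
# outer side and wetted chamber lining on its inner side; suture-band wall
# triangles are plain external wall for loading purposes (the band tag lives
# on nodes).  Septa expose gas-filled chamber faces except the final septum,
# whose adapertural (outer/adoral) side faces the body chamber water column.
OUTER_FACE_LABEL = {
    EXTERNAL_WALL: EXTERNAL_WALL,
    BODY_CHAMBER_INTERIOR: EXTERNAL_WALL,
    SUTURE_BAND: EXTERNAL_WALL,
    FINAL_SEPTUM_ADAPERTURAL: FINAL_SEPTUM_ADAPERTURAL,
    SEPTUM_INTERNAL: SEPTUM_INTERNAL,
    FORAMEN_RIM: SEPTUM_INTERNAL,
    VALIDATION: VALIDATION,
}

#: structural group of each mid-surface region; extrusion directions at
#: wall-septum junction vertices average the two structures' unit normals
#: with equal weight so neither structure's wedges invert.
STRUCTURE_OF = {
    EXTERNAL_WALL: "wall",
    BODY_CHAMBER_INTERIOR: "wall",
    SUTURE_BAND: "wall",
    FINAL_SEPTUM_ADAPERTURAL: "septum",
    SEPTUM_INTERNAL: "septum",
    FORAMEN_RIM: "septum",
    VALIDATION: "validation",
}

INNER_FACE_LABEL = {
    EXTERNAL_WALL: WALL_INTERIOR,
    BODY_CHAMBER_INTERIOR: BODY_CHAMBER_INTERIOR,
    SUTURE_BAND: WALL_INTERIOR,
    FINAL_SEPTUM_ADAPERTURAL: FINAL_SEPTUM_ADAPICAL,
    SEPTUM_INTERNAL: SEPTUM_INTERNAL,
    FORAMEN_RIM: SEPTUM_INTERNAL,
    VALIDATION: VALIDATION,
}
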