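"""Published validation results for the reference-sample cohorts.

Integer CN calls per assay for the copy-neutral and structural-variant
Coriell samples, plus the two probe-interference cases where only the raw
calculated CN (out of the valid window) was reported. These are the frozen
oracle values the forward model and pipeline must reproduce.

Per-plex entries are ``(ref_copies, var_copies)`` for the GT target;
``g.4181C`` is the consensus variant-only exon-9 count across the sample's
plexes.
"""

# Copy-neutral (CN = 2) cohort.
TABLE_COPY_NEUTRAL = {
    "NA17111": {
        "diplotype": "*1/*1",
        "CN_2851": (2, 0), "CN_1847": (2, 0), "CN_100": (2, 0),
        "CN_1022": (2, 0), "CN_3184": (2, 0), "CN_2989": (2, 0),
        "g.4181C": 0,
    },
    "NA18966": {"diplotype": "*1/*2", "CN_2851": (1, 1), "g.4181C": 1},
    "NA06991": {"diplotype": "*1/*4", "CN_1847": (1, 1), "CN_100": (1, 1),
                "g.4181C": 1},
    "HG03313": {"diplotype": "*29/*154", "CN_1022": (1, 1), "CN_3184": (1, 1),
                "g.4181C": 2},
    "NA19316": {"diplotype": "*2/*158", "CN_2989": (1, 1), "g.4181C": 2},
}

# Structural-variant cohort (duplications, multiplications, hybrids).
TABLE_SV = {
    "NA19685": {"diplotype": "*1/*2x2", "CN_2851": (1, 2), "g.4181C": 2},
    "NA19920": {"diplotype": "*1/*4x2", "CN_2851": (3, 0), "CN_1847": (1, 2),
                "CN_100": (1, 2), "g.4181C": 2},
    "NA24217": {"diplotype": "*2/*41x3", "CN_2851": (0, 4), "CN_2989": (1, 3),
                "g.4181C": 4},
    "NA19224": {"diplotype": "*2x2/*17", "CN_2851": (0, 3), "CN_1022": (2, 1),
                "CN_3184": (3, 0), "g.4181C": 3},
    "NA19109": {"diplotype": "*2x2/*29", "CN_3184": (2, 1), "g.4181C": 3},
    "NA17113": {"diplotype": "*17x2/*45", "CN_1022": (1, 2), "g.4181C": 3},
    "NA07439": {"diplotype": "*4x2/*41", "CN_1847": (1, 2), "CN_2989": (2, 1),
                "g.4181C": 3},
    "NA23297": {"diplotype": "*10x2/*17", "CN_100": (1, 2), "CN_1022": (2, 1),
                "g.4181C": 3},
    "NA21781": {"diplotype": "*2x2/*68+*4", "CN_2851": (1, 2),
                "CN_1847": (2, 1), "CN_100": (2, 2), "g.4181C": 3},
    "NA23246": {"diplotype": "*10x2/*36+*10", "CN_100": (0, 4), "g.4181C": 3},
}

# Probe-interference cases: calculated CN (not calls) for samples carrying
# g.1870T>C, which disrupts the g.1847G (reference-allele) probe. Values per
# plex are {channel: calculated CN}; g.1847G falls outside the valid window.
TABLE_INTERFERENCE = {
    "HG00123": {
        "diplotype": "*1/*4",  # *1.005/*4.004
        "CN_1847": {"g.1847G": 0.48, "g.1847A": 1.00, "g.4181C": 0.93},
        "CN_100": {"g.100C": 0.98, "g.100T": 1.00, "g.4181C": 0.98},
    },
    "NA19121": {
        "diplotype": "*1/*4x2",  # *1.068/*4x2
        "CN_1847": {"g.1847G": 0.62, "g.1847A": 2.05, "g.4181C": 1.91},
        "CN_100": {"g.100C": 1.00, "g.100T": 1.95, "g.4181C": 1.97},
    },
}


def plexes_of(entry: dict) -> list[str]:
    return [k for k in entry if k.startswith("CN_")]
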