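"""Central defaults for the screening pipeline.

All thresholds and parameters that govern behaviour live here so that a
run can be audited from one place.  Units are noted per entry.
"""

# --- activity curation -------------------------------------------------
ACTIVE_KI_NM = 100.0      # Ki <= 100 nM  -> active
INACTIVE_KI_NM = 1000.0   # Ki > 1000 nM  -> inactive
IC50_TO_KI = 0.5          # Ki assumed = IC50 / 2

# unit multipliers to nM for Ki / IC50 inputs
UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "M": 1e9}

# preference order over (species, is_ki) strata when aggregating
# duplicate activity records for one compound; earlier wins.
STRATUM_ORDER = [
    ("human", True),
    ("human", False),
    ("rat", True),
    ("rat", False),
    ("other", True),
    ("other", False),
]

# --- fingerprints ------------------------------------------------------
M2D_RADIUS = 2            # bond radius of the atom environment
P3D_BIN_WIDTH = 1.0       # Angstrom per distance bin
P3D_MAX_DIST = 15.0       # distances above this clamp to the top bin

# --- clustering --------------------------------------------------------
LINKAGE = "average"
MIN_CLUSTER_SIZE = 3      # smaller clusters pool into the special class
MAX_SPLITS = 4            # recursive splitting rounds for oversized clusters
MAX_SIZE_FRACTION = 0.2   # cluster > 20% of the input counts as oversized

# --- diversity selection ----------------------------------------------
SPHERE_RADIUS = 0.5       # Soergel distance sphere-exclusion radius
REPS_PER_50 = 0.94        # representatives per 50 cluster members
MIN_REPS = 4
N_PER_ROLE = 200          # actives / decoys / assumed-inactives per test set

# --- pharmacophore modelling -------------------------------------------
MATCH_RMSD_TOL = 2.0      # Angstrom, hypothesis/conformer match tolerance
K_RANGE = (4, 7)          # hypothesis feature counts considered
HYP_MAX_SPAN = 15.0       # Angstrom, max inter-feature distance in a candidate
MATCH_RATE_MIN = 0.5      # candidate must map at least half the input reps
CANDIDATE_CAP = 5000      # per-representative enumeration cap (then sample)

# conformer-generation contract (honoured by external engines)
CONF_PER_ROTATABLE = 10
CONF_MAX = 100
CONF_ENERGY_WINDOW = 10.0  # kcal/mol

# feature perception SMARTS (open, documented definitions)
FEATURE_SMARTS = {
    # hydrogen-bond acceptor: N/O with a lone pair, not positively charged
    "A": "[$([O;H1;v2]),$([O;H0;v2;!$(O=N-*)]),$([O;-]),$([N;v3;!$(N-*=[O,N,P,S]);!$([N+])]),$([n;H0;+0])]",
    # hydrogen-bond donor heavy atom
    "D": "[$([N;!H0;v3;!$([N+])]),$([O;H1;+0]),$([n;!H0;+0])]",
    # positively charged / protonatable nitrogen centre
    "P": "[$([N+;!$(N=*)]),$([N;H2;v3;!$(N-[!#6])]),$([N;H0,H1;v3;!$(N-[!#6;!#1]);!$(N-a);!$(N-C=[O,N,S])])]",
    # hydrophobic atom (grouped into centroids of connected components)
    "H": "[$([C;D3,D4;!$(C-[!#6;!#1])]),$([C;H2,H3;!$(C-[!#6;!#1])]),$([S;D2;$(S(-[#6])-[#6])]),F,Cl,Br,I]",
    # aromatic ring -> centroid (computed from ring info, not SMARTS)
    "R": None,
}

# --- ensemble optimisation ---------------------------------------------
SUBSET_BUDGET = 5_000_000  # max k-subsets an exhaustive search may enumerate
RANDOM_DRAWS = 10          # draws in the random-combination benchmark
REPORT_DECIMALS = 3
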