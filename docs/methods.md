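# Methods

## Data model

Positional data is a long-form table of `(time_s, player_id, team, x_m,
y_m)` samples at a fixed rate (default 10 Hz) on a rectangular pitch with
the origin at a corner: x runs longitudinally (goal to goal, `[0,
length]`), y transversely (`[0, width]`). The default pitch is 105 × 68 m,
the standard full-size field. All players share one uniform time grid
`t = t₀ + k/rate`.

On import, timestamps are snapped to the nearest grid point; two samples
of one player landing on the same grid point is an alignment error (the
data is then not uniformly sampled at the declared rate). Out-of-bounds
positions are clamped to the pitch with a logged warning — jitter past the
touchline is normal tracking behavior — unless strict mode is on. Interior
gaps up to `max_gap_s` (default 0.5 s) are filled by linear interpolation;
longer gaps are rejected rather than silently invented.

Analysis groups are free, ordered player selections (e.g. "3 forwards vs
4 defenders"); the only constraint is a minimum size — 2 for
centroid-based metrics, 3 for hull areas. Goalkeeper exclusion, or any
other role logic, is the analyst's job via group composition.

## Collective metrics

Per frame, for a group of N members at positions `pᵢ`:

- centroid `c = (1/N) Σ pᵢ` (unweighted mean; captures collective
  forward/backward and lateral movement);
- stretch index `SI = (1/N) Σ ‖pᵢ − c‖`, with rate `dSI/dt` by centered
  finite differences (one-sided at series ends, via `numpy.gradient`);
- surface area: convex-hull area in m². The hull is a Graham scan — pivot
  at lowest y then lowest x, polar-angle sort with collinear points
  ordered by pivot distance, strict left turns only, so points interior to
  a hull edge are not vertices. All-collinear inputs give a degenerate
  hull flagged with area 0 (not an error: a perfectly flat line of players
  is a legitimate frame). Area is the shoelace formula on the CCW
  vertices.
- overlap of two hulls by Sutherland–Hodgman half-plane clipping, valid
  because both inputs are convex; the result is ≤ min of the two areas;
- team length/width: max−min of x and y respectively (axis-aligned by
  definition, hence deliberately not rotation-invariant).

These satisfy, and the tests assert, translation equivariance/invariance,
rotation invariance of SI and area, `s`/`s²` scaling of lengths/areas
under uniform scaling about the centroid, and `area ≤ length × width` per
frame.

## Individual kinematics

Speed at frame i is the Euclidean step from frame i−1 divided by the step
duration; the first frame duplicates the second so the series keeps one
value per sample. Raw 10 Hz differentiation amplifies tracking noise, so a
centered moving average (default window 0.5 s, i.e. 5 taps at 10 Hz,
truncated at the edges) is applied; the window is configurable and 0
disables smoothing (used wherever exact step/distance identities matter).

Speeds are discretized into five paces separated at 0.2, 2.1, 3.8 and
6.1 m/s. Intervals are half-open `[lower, upper)` with the boundary
assigned upward — a speed of exactly 2.1 m/s is Jogging — making the map
total and monotone. Classification can be cached on the dataset at import
time (`attach_paces`); changing the scheme means re-importing, which keeps
every downstream view consistent.

Distance by pace attributes each step's length `v·Δt` (at the smoothed
speed) to that speed's class, so per-class distances conserve the total
exactly. Heat maps bin samples on a regular grid (default 1 m) covering
the pitch exactly — the last row/column may be a partial bin — and count
samples (occupancy) or accumulate `1/rate` seconds per sample at a chosen
pace.

## Synchrony

Coordination between two players is measured on their
distance-to-group-centroid series, treated as coupled oscillators. Each
signal is mean-centered (optionally linearly detrended — the default in
`coordination_profile`, since a drifting baseline distorts the Hilbert
phase), transformed to its analytic representation (`scipy.signal.hilbert`),
and the relative phase is taken as `arg(hₐ · conj(h_b))` — the exactly
wrapped phase difference in (−180°, 180°], with no unwrap artifacts. It is
invariant to positive rescaling and offsets of either input. The analytic
signal is unreliable near the series ends, so the first and last 5% of
frames are flagged and excluded from circular summaries (configurable).
Circular summaries report the direction of the mean unit vector and the
resultant length in [0, 1]; a resultant below 1e−12 (e.g. antipodal
angles) flags the mean as undefined instead of reporting noise.

ApEn follows the classic formulation: `Φᵏ(r)` is the mean log fraction of
length-k windows within Chebyshev distance r of each window, self-matches
included (so no log 0 and a constant series scores exactly 0), and
`ApEn = Φᵐ − Φᵐ⁺¹`. Defaults are the field standard m=2, r=0.2×SD; r can
also be absolute, which is required for constant series (their SD is 0).
Two numerical caveats, both verified against a direct O(N²) reference:

- ApEn is *not* guaranteed non-negative for every input: if r is so tight
  that windows match only themselves, the differing window counts at m
  and m+1 give `ApEn = ln((N−m)/(N−m+1)) < 0`. This floor is sharp and
  tiny; at practical lengths (N ≥ ~100 with r = 0.2 SD) ApEn is
  non-negative in every test we run.
- ApEn is not monotone in r: it rises as r leaves the isolated-window
  regime, peaks, and then decays to exactly 0 once r covers the whole
  range. Tests assert the decay over the large-r tail, not global
  monotonicity.

The often-quoted 0–2 range is an empirical expectation for movement data,
not a bound; the package asserts only the properties above.

## Synthetic data

The generator emulates a tracked match half: default 2700 s at 10 Hz
(27,000 samples per player) on a 105 × 68 m pitch. Agents follow
prescribed kinematics — anchor, linear waypoint drift, per-axis sinusoidal
oscillation with amplitude/frequency/phase, or a piecewise target-speed
shuttle along the longitudinal axis with reflection at the bounds — plus
additive i.i.d. Gaussian positional noise applied before clamping to the
pitch. Each agent draws from a substream keyed by `(seed, agent index)`,
so output is bit-reproducible and adding an agent never perturbs existing
trajectories.

Three scripted scenarios inject recoverable ground truth: `goal_buildup`
(linearly advancing attackers overtake retreating defenders; within each
trio the x-oscillations are equal-amplitude at phases 120° apart so they
cancel in the centroid, keeping the logged crossover time recoverable to
±0.5 s under 0.2 m jitter), `coordination_break` (two defenders oscillate
in phase about the group centroid except in a logged window where one is
ramped to anti-phase over 2 s), and `expansion_contraction` (a hexagonal
formation scaled radially, piecewise-linearly out and back).

What the generator does *not* emulate: tactical decision-making, ball
interaction, collisions/occlusion dropouts, autocorrelated tracking error,
or heterogeneous player roles. Passing recovery tests therefore shows the
estimators correctly invert the generative model under realistic sampling
and jitter — not that the metrics capture real tactical behavior, which is
a claim about football, not code.

Scenario noise SDs (0.1–0.3 m) were fixed once as typical optical-tracking
jitter; scenario durations are 60–120 s (a single passage of play), while
the full 2700 s half is used where the per-half sample count itself is the
quantity of interest. Event detection in examples and CLI summaries uses a
1 s moving average of the centroid difference (crossover) and an
illustrative, non-normative |phase| > 90° sustained ≥ 2 s rule
(coordination break).

## Interfaces and conventions

Long-form positional CSV `time_s,player_id,team,x_m,y_m` (UTF-8, dot
decimal); metric series CSVs lead with `time_s`; heat maps export as dense
matrices under a two-line comment header; YAML config can override pitch,
rate, pace scheme, ApEn parameters, smoothing and gap limits. CLI exit
codes: 2 configuration/domain, 3 validation/selection, 4 degenerate
computation. Floats are written at 12 significant digits, making
write→read round trips exact to well below 1e−9.

## Known limitations

- Hull and overlap computations loop per frame in Python; at 27,000
  frames × 10 players this is seconds, not milliseconds. Fine for analysis
  sessions, not for real-time streaming.
- Relative phase assumes both signals genuinely oscillate; constant or
  near-constant inputs raise a degenerate-signal error rather than
  returning meaningless angles (a perfectly in-phase noise-free pair
  yields a constant phase series, whose ApEn then needs an absolute r).
- No multi-agent (cluster-phase) synchrony, windowed coherence, Voronoi
  areas of influence, or ball/event data.
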