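# On-disk session format

A dataset directory contains one *session directory per recording*
plus an index:

```
dataset/
  dataset.json
  P01__prone_lying__000/
    manifest.json
    lower_back__accelerometer.csv
    lower_back__gyroscope.csv
    lower_back__magnetometer.csv
    lower_back__quaternion.csv
    lower_back__pressure.csv
    ...
  P01__prone_extension__001/
    ...
```

## dataset.json

| field          | type     | meaning                                   |
|----------------|----------|-------------------------------------------|
| `n_recordings` | int      | number of session directories              |
| `sessions`     | [string] | session directory names, dataset order     |
| `metadata`     | object   | free-form provenance (seed, protocol, ...) |

A directory without `dataset.json` is read by scanning for
subdirectories containing a `manifest.json`; a directory that itself
contains a `manifest.json` is read as a single-recording dataset.

## manifest.json (one per session)

| field            | type     | meaning                            |
|------------------|----------|-------------------------------------|
| `participant_id` | string   | group key for grouped CV            |
| `label`          | string   | activity-class name (one per bout)  |
| `duration_s`     | float    | last timestamp across streams       |
| `streams`        | [object] | one entry per stream file           |

Each stream entry: `file` (CSV filename), `location` (one of wrist,
left_shoulder, right_shoulder, upper_back, lower_back, left_thigh,
right_ankle, right_ear), `channel` (accelerometer | gyroscope |
magnetometer | quaternion | pressure), `rate_hz`.

## Stream CSVs

Header `t,<axis1>,...` with axes fixed per channel — `x,y,z` for
accelerometer (m/s²), gyroscope (rad/s) and magnetometer (µT);
`w,x,y,z` for unit quaternions (Hamilton, scalar-first,
earth-to-sensor); `p` for pressure (Pa). Timestamps are seconds from
the session start, strictly increasing. Values are written with
`repr` precision, so a write/read round trip is bit-exact.
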