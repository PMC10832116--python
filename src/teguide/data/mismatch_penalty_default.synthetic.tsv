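# name=synthetic-linear-position
position	ref	obs	factor
1	A	C	0.9
1	A	G	0.9
1	A	T	0.9
1	C	A	0.9
1	C	G	0.9
1	C	T	0.9
1	G	A	0.9
1	G	C	0.9
1	G	T	0.9
1	T	A	0.9
1	T	C	0.9
1	T	G	0.9
2	A	C	0.8579
2	A	G	0.8579
2	A	T	0.8579
2	C	A	0.8579
2	C	G	0.8579
2	C	T	0.8579
2	G	A	0.8579
2	G	C	0.8579
2	G	T	0.8579
2	T	A	0.8579
2	T	C	0.8579
2	T	G	0.8579
3	A	C	0.8158
3	A	G	0.8158
3	A	T	0.8158
3	C	A	0.8158
3	C	G	0.8158
3	C	T	0.8158
3	G	A	0.8158
3	G	C	0.8158
3	G	T	0.8158
3	T	A	0.8158
3	T	C	0.8158
3	T	G	0.8158
4	A	C	0.7737
4	A	G	0.7737
4	A	T	0.7737
4	C	A	0.7737
4	C	G	0.7737
4	C	T	0.7737
4	G	A	0.7737
4	G	C	0.7737
4	G	T	0.7737
4	T	A	0.7737
4	T	C	0.7737
4	T	G	0.7737
5	A	C	0.7316
5	A	G	0.7316
5	A	T	0.7316
5	C	A	0.7316
5	C	G	0.7316
5	C	T	0.7316
5	G	A	0.7316
5	G	C	0.7316
5	G	T	0.7316
5	T	A	0.7316
5	T	C	0.7316
5	T	G	0.7316
6	A	C	0.6895
6	A	G	0.6895
6	A	T	0.6895
6	C	A	0.6895
6	C	G	0.6895
6	C	T	0.6895
6	G	A	0.6895
6	G	C	0.6895
6	G	T	0.6895
6	T	A	0.6895
6	T	C	0.6895
6	T	G	0.6895
7	A	C	0.6474
7	A	G	0.6474
7	A	T	0.6474
7	C	A	0.6474
7	C	G	0.6474
7	C	T	0.6474
7	G	A	0.6474
7	G	C	0.6474
7	G	T	0.6474
7	T	A	0.6474
7	T	C	0.6474
7	T	G	0.6474
8	A	C	0.6053
8	A	G	0.6053
8	A	T	0.6053
8	C	A	0.6053
8	C	G	0.6053
8	C	T	0.6053
8	G	A	0.6053
8	G	C	0.6053
8	G	T	0.6053
8	T	A	0.6053
8	T	C	0.6053
8	T	G	0.6053
9	A	C	0.5632
9	A	G	0.5632
9	A	T	0.5632
9	C	A	0.5632
9	C	G	0.5632
9	C	T	0.5632
9	G	A	0.5632
9	G	C	0.5632
9	G	T	0.5632
9	T	A	0.5632
9	T	C	0.5632
9	T	G	0.5632
10	A	C	0.5211
10	A	G	0.5211
10	A	T	0.5211
10	C	A	0.5211
10	C	G	0.5211
10	C	T	0.5211
10	G	A	0.5211
10	G	C	0.5211
10	G	T	0.5211
10	T	A	0.5211
10	T	C	0.5211
10	T	G	0.5211
11	A	C	0.4789
11	A	G	0.4789
11	A	T	0.4789
11	C	A	0.4789
11	C	G	0.4789
11	C	T	0.4789
11	G	A	0.4789
11	G	C	0.4789
11	G	T	0.4789
11	T	A	0.4789
11	T	C	0.4789
11	T	G	0.4789
12	A	C	0.4368
12	A	G	0.4368
12	A	T	0.4368
12	C	A	0.4368
12	C	G	0.4368
12	C	T	0.4368
12	G	A	0.4368
12	G	C	0.4368
12	G	T	0.4368
12	T	A	0.4368
12	T	C	0.4368
12	T	G	0.4368
13	A	C	0.3947
13	A	G	0.3947
13	A	T	0.3947
13	C	A	0.3947
13	C	G	0.3947
13	C	T	0.3947
13	G	A	0.3947
13	G	C	0.3947
13	G	T	0.3947
13	T	A	0.3947
13	T	C	0.3947
13	T	G	0.3947
14	A	C	0.3526
14	A	G	0.3526
14	A	T	0.3526
14	C	A	0.3526
14	C	G	0.3526
14	C	T	0.3526
14	G	A	0.3526
14	G	C	0.3526
14	G	T	0.3526
14	T	A	0.3526
14	T	C	0.3526
14	T	G	0.3526
15	A	C	0.3105
15	A	G	0.3105
15	A	T	0.3105
15	C	A	0.3105
15	C	G	0.3105
15	C	T	0.3105
15	G	A	0.3105
15	G	C	0.3105
15	G	T	0.3105
15	T	A	0.3105
15	T	C	0.3105
15	T	G	0.3105
16	A	C	0.2684
16	A	G	0.2684
16	A	T	0.2684
16	C	A	0.2684
16	C	G	0.2684
16	C	T	0.2684
16	G	A	0.2684
16	G	C	0.2684
16	G	T	0.2684
16	T	A	0.2684
16	T	C	0.2684
16	T	G	0.2684
17	A	C	0.2263
17	A	G	0.2263
17	A	T	0.2263
17	C	A	0.2263
17	C	G	0.2263
17	C	T	0.2263
17	G	A	0.2263
17	G	C	0.2263
17	G	T	0.2263
17	T	A	0.2263
17	T	C	0.2263
17	T	G	0.2263
18	A	C	0.1842
18	A	G	0.1842
18	A	T	0.1842
18	C	A	0.1842
18	C	G	0.1842
18	C	T	0.1842
18	G	A	0.1842
18	G	C	0.1842
18	G	T	0.1842
18	T	A	0.1842
18	T	C	0.1842
18	T	G	0.1842
19	A	C	0.1421
19	A	G	0.1421
19	A	T	0.1421
19	C	A	0.1421
19	C	G	0.1421
19	C	T	0.1421
19	G	A	0.1421
19	G	C	0.1421
19	G	T	0.1421
19	T	A	0.1421
19	T	C	0.1421
19	T	G	0.1421
20	A	C	0.1
20	A	G	0.1
20	A	T	0.1
20	C	A	0.1
20	C	G	0.1
20	C	T	0.1
20	G	A	0.1
20	G	C	0.1
20	G	T	0.1
20	T	A	0.1
20	T	C	0.1
20	T	G	0.1
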