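genotype_label: corrected
anchors:
  div:
  - 4
  - 5
  - 6
  - 7
  - 8
  - 9
  - 10
  - 11
  - 12
  - 13
  - 14
  - 15
  - 16
  - 17
  - 18
  - 19
  - 20
  - 21
  - 22
  - 23
  - 24
  - 25
  - 26
  - 27
  - 28
  - 29
  - 30
  - 31
  - 32
  - 33
  - 34
  - 35
  - 36
  - 37
  - 38
  - 39
  - 40
  - 41
  - 42
  tonic_rate:
  - 0.22
  - 0.288889
  - 0.357778
  - 0.393333
  - 0.459444
  - 0.440466
  - 0.469844
  - 0.60339
  - 1.184935
  - 1.648837
  - 2.0
  - 1.51037
  - 2.0
  - 3.652206
  - 2.0
  - 0.828619
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  burst_rate:
  - 1.5
  - 1.666667
  - 1.833333
  - 2.0
  - 2.166667
  - 2.457854
  - 2.614508
  - 2.862695
  - 3.120837
  - 3.140865
  - 3.446124
  - 7.422301
  - 8.997259
  - 5.548164
  - 14.273529
  - 16.950807
  - 14.161479
  - 14.795535
  - 15.28869
  - 15.683214
  - 16.006006
  - 16.274999
  - 14.945519
  - 13.805964
  - 12.81835
  - 11.954188
  - 11.191692
  - 10.513918
  - 9.907489
  - 9.361703
  - 8.867896
  - 8.418981
  - 8.009102
  - 7.633379
  - 7.287714
  - 5.651732
  - 4.069956
  - 2.602183
  - 1.16662
  burst_duration:
  - 0.06
  - 0.066667
  - 0.073333
  - 0.08
  - 0.086667
  - 0.093333
  - 0.1
  - 0.35
  - 0.366667
  - 0.383333
  - 0.4
  - 0.34
  - 0.28
  - 0.22
  - 0.33
  - 0.44
  - 0.55
  - 0.629474
  - 0.708947
  - 0.788421
  - 0.867895
  - 0.947368
  - 1.026842
  - 1.106316
  - 1.185789
  - 1.265263
  - 1.344737
  - 1.42421
  - 1.503684
  - 1.583158
  - 1.662631
  - 1.742105
  - 1.821579
  - 1.901052
  - 1.980526
  - 2.06
  - 2.139473
  - 2.218947
  - 2.298421
  intra_burst_isi:
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  - 0.02
  active_electrode_prob:
  - 0.1
  - 0.1252
  - 0.1504
  - 0.1756
  - 0.2008
  - 0.3006
  - 0.4004
  - 0.5002
  - 0.6
  - 0.6925
  - 0.785
  - 0.8775
  - 0.97
  - 0.968571
  - 0.967143
  - 0.965714
  - 0.964286
  - 0.962857
  - 0.961429
  - 0.96
  - 0.958571
  - 0.957143
  - 0.955714
  - 0.954286
  - 0.952857
  - 0.951429
  - 0.95
  - 0.953
  - 0.956
  - 0.959
  - 0.962
  - 0.965
  - 0.968
  - 0.971
  - 0.9568
  - 0.9426
  - 0.9284
  - 0.9142
  - 0.9
  network_burst_rate:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.546908
  - 3.09
  - 4.331599
  - 1.0
  - 4.10811
  - 5.321108
  - 5.602982
  - 4.917713
  - 5.256347
  - 5.527554
  - 5.749856
  - 5.935551
  - 5.451505
  - 5.036334
  - 4.676296
  - 4.361076
  - 4.082784
  - 3.828808
  - 3.601323
  - 4.24544
  - 4.013342
  - 3.802063
  - 3.608881
  - 4.575365
  - 4.395957
  - 3.308317
  - 3.372141
  - 1.883615
  - 1.120274
  network_burst_duration:
  - 0.3
  - 0.4
  - 0.5
  - 0.6
  - 0.7
  - 0.8
  - 0.825
  - 0.85
  - 0.875
  - 0.9
  - 0.925
  - 0.95
  - 0.975
  - 1.0
  - 1.351577
  - 1.703154
  - 2.054731
  - 2.406309
  - 2.757886
  - 3.109463
  - 3.46104
  - 3.812617
  - 4.113437
  - 4.414258
  - 4.715078
  - 5.015898
  - 5.316719
  - 5.617539
  - 5.918359
  - 6.21918
  - 6.52
  - 6.08
  - 5.64
  - 5.2
  - 4.76
  - 4.32
  - 3.88
  - 3.44
  - 3.0
  network_participation:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 0.25
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
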