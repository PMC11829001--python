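e29d0a1591a393a2d809be03cdd4ea6fdbeb8228b197874de229036285ffd0b0  table3_dockq.tsv
eca85cff7991fb3096e47667e716e3d76b99a1bbee4be5473276777acc029181  table4_best_rank.tsv
b8fbdfb767eeca3474f83f245ce8f32908a752c1b303c479d19db7eece18ae26  table5_first_acceptable.tsv
982e5f0ea9e8e4c5014854e2eed36207dd36e99d031e80ae0ce3eab80e0bc55d  table6_grid_improvement.tsv
4bc829a052df6f83e20ca71fbf1fa11d43bfa4e0c4f55c87df20dd4b8f4cc17c  table7_selected_transforms.tsv
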