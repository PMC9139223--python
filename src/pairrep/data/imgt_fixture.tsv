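# Human TRA/TRB germline V and J segments with IMGT-style functionality classes.
# Editable fixture: functionality assignments are IMGT-release dependent.
name	functionality
TRAV1-1	functional
TRAV1-2	functional
TRAV2	functional
TRAV3	functional
TRAV4	functional
TRAV5	functional
TRAV6	functional
TRAV7	functional
TRAV8-1	functional
TRAV8-2	functional
TRAV8-3	functional
TRAV8-4	functional
TRAV8-5	pseudogene
TRAV8-6	functional
TRAV8-7	ORF
TRAV9-1	functional
TRAV9-2	functional
TRAV10	functional
TRAV11	pseudogene
TRAV12-1	functional
TRAV12-2	functional
TRAV12-3	functional
TRAV13-1	functional
TRAV13-2	functional
TRAV14/DV4	functional
TRAV15	pseudogene
TRAV16	functional
TRAV17	functional
TRAV18	functional
TRAV19	functional
TRAV20	functional
TRAV21	functional
TRAV22	functional
TRAV23/DV6	functional
TRAV24	functional
TRAV25	functional
TRAV26-1	functional
TRAV26-2	functional
TRAV27	functional
TRAV28	pseudogene
TRAV29/DV5	functional
TRAV30	functional
TRAV31	pseudogene
TRAV32	pseudogene
TRAV33	pseudogene
TRAV34	functional
TRAV35	functional
TRAV36/DV7	functional
TRAV37	pseudogene
TRAV38-1	functional
TRAV38-2/DV8	functional
TRAV39	functional
TRAV40	functional
TRAV41	functional
TRAJ1	functional
TRAJ2	functional
TRAJ3	functional
TRAJ4	functional
TRAJ5	functional
TRAJ6	functional
TRAJ7	functional
TRAJ8	functional
TRAJ9	functional
TRAJ10	functional
TRAJ11	functional
TRAJ12	functional
TRAJ13	functional
TRAJ14	functional
TRAJ15	functional
TRAJ16	functional
TRAJ17	functional
TRAJ18	functional
TRAJ19	functional
TRAJ20	functional
TRAJ21	functional
TRAJ22	functional
TRAJ23	functional
TRAJ24	functional
TRAJ25	functional
TRAJ26	functional
TRAJ27	functional
TRAJ28	functional
TRAJ29	functional
TRAJ30	functional
TRAJ31	functional
TRAJ32	functional
TRAJ33	functional
TRAJ34	functional
TRAJ35	functional
TRAJ36	functional
TRAJ37	functional
TRAJ38	functional
TRAJ39	functional
TRAJ40	functional
TRAJ41	functional
TRAJ42	functional
TRAJ43	functional
TRAJ44	functional
TRAJ45	functional
TRAJ46	functional
TRAJ47	functional
TRAJ48	functional
TRAJ49	functional
TRAJ50	functional
TRAJ51	pseudogene
TRAJ52	functional
TRAJ53	functional
TRAJ54	functional
TRAJ55	pseudogene
TRAJ56	functional
TRAJ57	functional
TRAJ58	functional
TRAJ59	functional
TRAJ60	pseudogene
TRAJ61	functional
TRBV1	pseudogene
TRBV2	functional
TRBV3-1	functional
TRBV3-2	pseudogene
TRBV4-1	functional
TRBV4-2	functional
TRBV4-3	functional
TRBV5-1	functional
TRBV5-3	ORF
TRBV5-4	functional
TRBV5-5	functional
TRBV5-6	functional
TRBV5-7	ORF
TRBV5-8	functional
TRBV6-1	functional
TRBV6-2	functional
TRBV6-3	functional
TRBV6-4	functional
TRBV6-5	functional
TRBV6-6	functional
TRBV6-7	ORF
TRBV6-8	functional
TRBV6-9	functional
TRBV7-1	ORF
TRBV7-2	functional
TRBV7-3	functional
TRBV7-4	functional
TRBV7-6	functional
TRBV7-7	functional
TRBV7-8	functional
TRBV7-9	functional
TRBV9	functional
TRBV10-1	functional
TRBV10-2	functional
TRBV10-3	functional
TRBV11-1	functional
TRBV11-2	functional
TRBV11-3	functional
TRBV12-1	pseudogene
TRBV12-2	pseudogene
TRBV12-3	functional
TRBV12-4	functional
TRBV12-5	functional
TRBV13	functional
TRBV14	functional
TRBV15	functional
TRBV16	functional
TRBV17	ORF
TRBV18	functional
TRBV19	functional
TRBV20-1	functional
TRBV21-1	pseudogene
TRBV23-1	ORF
TRBV24-1	functional
TRBV25-1	functional
TRBV27	functional
TRBV28	functional
TRBV29-1	functional
TRBV30	functional
TRBJ1-1	functional
TRBJ1-2	functional
TRBJ1-3	functional
TRBJ1-4	functional
TRBJ1-5	functional
TRBJ1-6	functional
TRBJ2-1	functional
TRBJ2-2	functional
TRBJ2-3	functional
TRBJ2-4	functional
TRBJ2-5	functional
TRBJ2-6	functional
TRBJ2-7	functional
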